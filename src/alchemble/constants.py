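"""Physical constants and package-wide defaults (kcal/mol energy units)."""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_MOL_K: float = 1.9872e-3

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE: float = 298.15

#: Default experimental uncertainty assigned to affinity differences with no
#: reported error: 0.3 log units of activity at 298.15 K, in kcal/mol.
DEFAULT_EXP_ERR_KCAL: float = 0.41

#: Affinity-difference bin edges (kcal/mol) used in the underestimation
#: analysis; the printed 1-log-unit and 2-log-unit boundaries.
DEFAULT_BIN_EDGES: tuple[float, float] = (1.37, 2.73)

#: Schema version stamped into every JSON report this package writes.
SCHEMA_VERSION: str = "1"


def kt_kcal(temperature: float) -> float:
    """Thermal energy kT in kcal/mol at ``temperature`` kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
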