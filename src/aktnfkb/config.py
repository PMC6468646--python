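"""Repository-wide conventions and conversion constants.

Units are nM for concentrations and hours for time everywhere.  Doses quoted
in ng/mL (as in cell-culture protocols) are converted to molarity with the
molecular weight recorded here rather than a number buried in the code.
"""

#: molecular weight of mature EGF, kDa
EGF_MW_KDA = 6.2

#: sparse densitometry sampling grid used for blot-style observations, hours
DEFAULT_BLOT_TIMES = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0)


def ng_per_ml_to_nM(ng_per_ml: float, mw_kda: float = EGF_MW_KDA) -> float:
    """Convert a mass dose to molar concentration: (ng/mL) / kDa = nM."""
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return ng_per_ml / mw_kda
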