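"""Independent brute-force staging oracle.

Written directly from the prioritized staging-criteria table as a flat
if/elif cascade over complete inputs (no missing values), deliberately not
sharing code with the engine.  Like the engine, the grade-group-1 row with
PSA below 20 covers T2b/T2c below 10 once stage I has claimed T1-T2a.
"""

T_ALL = ("T1", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T2c", "T3", "T3a", "T3b", "T4")


def oracle_stage(t: str, n: str, m: str, gg: int, psa: float) -> str:
    if m == "M1":
        return "IVB"
    if n == "N1":
        return "IVA"
    if gg == 5:
        return "IIIC"
    if t in ("T3", "T3a", "T3b", "T4"):
        return "IIIB"
    if psa >= 20:
        return "IIIA"
    if gg == 1:
        if t in ("T1", "T1a", "T1b", "T1c", "T2", "T2a") and psa < 10:
            return "I"
        return "IIA"
    if gg == 2:
        return "IIB"
    return "IIC"
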