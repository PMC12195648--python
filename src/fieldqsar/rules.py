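"""Rule-based oral-druglikeness screening over a descriptor table.

Descriptors (MW, HBD, HBA, cLogP, TPSA, rotatable bonds, and optionally
logS and fraction Csp3) arrive as inputs — typically from an upstream
property predictor — and are screened against Lipinski's rule of five,
Veber's oral-bioavailability thresholds, and the six-axis bioavailability
radar ranges.  All boundary values are inclusive on the compliant side
(MW = 500 is not a violation; NRB = 10 passes Veber).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Radar axis -> (descriptor attribute, low, high).  SwissADME-style default
#: ranges; LIPO uses the supplied cLogP.
RADAR_RANGES: dict[str, tuple[str, float, float]] = {
    "LIPO": ("clogp", -0.7, 5.0),
    "SIZE": ("mw", 150.0, 500.0),
    "POLAR": ("tpsa", 20.0, 130.0),
    "FLEX": ("nrb", 0.0, 9.0),
    "INSOLU": ("logs", -6.0, 0.0),
    "INSATU": ("fcsp3", 0.25, 1.0),
}


@dataclass
class DescriptorRecord:
    compound_id: str
    mw: float      # g/mol
    hbd: int
    hba: int
    clogp: float
    tpsa: float    # A^2
    nrb: int
    logs: float | None = None   # optional, radar INSOLU axis
    fcsp3: float | None = None  # optional, radar INSATU axis

    def __post_init__(self):
        if not self.mw > 0:
            raise ValueError(f"{self.compound_id}: mw must be > 0")
        for name in ("hbd", "hba", "nrb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.compound_id}: {name} must be >= 0")


def lipinski(rec: DescriptorRecord) -> list[str]:
    """Rule-of-five violations: MW > 500, HBD > 5, HBA > 10, cLogP > 5."""
    for name in ("mw", "hbd", "hba", "clogp"):
        if getattr(rec, name) is None:
            raise ValueError(f"{rec.compound_id}: missing {name}")
    violations = []
    if rec.mw > 500:
        violations.append("MW>500")
    if rec.hbd > 5:
        violations.append("HBD>5")
    if rec.hba > 10:
        violations.append("HBA>10")
    if rec.clogp > 5:
        violations.append("cLogP>5")
    return violations


def veber(rec: DescriptorRecord) -> list[str]:
    """Veber violations: TPSA > 140 A^2 or more than 10 rotatable bonds."""
    for name in ("tpsa", "nrb"):
        if getattr(rec, name) is None:
            raise ValueError(f"{rec.compound_id}: missing {name}")
    violations = []
    if rec.tpsa > 140:
        violations.append("TPSA>140")
    if rec.nrb > 10:
        violations.append("NRB>10")
    return violations


def radar(rec: DescriptorRecord) -> dict[str, bool]:
    """Per-axis in-range flags of the bioavailability radar; axes whose
    descriptor was not supplied are omitted."""
    out = {}
    for axis, (attr, lo, hi) in RADAR_RANGES.items():
        val = getattr(rec, attr, None)
        if val is not None:
            out[axis] = lo <= val <= hi
    return out


def rule_report(records: list[DescriptorRecord]) -> pd.DataFrame:
    """One row per compound: violation lists and pass flags.

    ``lipinski_pass`` follows the classic at-most-one-violation reading;
    ``lipinski_strict`` requires none.
    """
    rows = []
    for rec in records:
        lip = lipinski(rec)
        veb = veber(rec)
        rad = radar(rec)
        rows.append({
            "compound_id": rec.compound_id,
            "lipinski_violations": ";".join(lip),
            "n_lipinski_violations": len(lip),
            "lipinski_pass": len(lip) <= 1,
            "lipinski_strict": len(lip) == 0,
            "veber_violations": ";".join(veb),
            "veber_pass": len(veb) == 0,
            "radar_pass": all(rad.values()) if rad else None,
        })
    return pd.DataFrame(rows)


def read_descriptor_csv(path) -> list[DescriptorRecord]:
    """Descriptor table: compound_id, mw, hbd, hba, clogp, tpsa, nrb
    (+ optional logs, fcsp3)."""
    df = pd.read_csv(path)
    recs = []
    for _, r in df.iterrows():
        recs.append(DescriptorRecord(
            compound_id=str(r["compound_id"]), mw=float(r["mw"]),
            hbd=int(r["hbd"]), hba=int(r["hba"]), clogp=float(r["clogp"]),
            tpsa=float(r["tpsa"]), nrb=int(r["nrb"]),
            logs=float(r["logs"]) if "logs" in df.columns and pd.notna(r["logs"]) else None,
            fcsp3=float(r["fcsp3"]) if "fcsp3" in df.columns and pd.notna(r["fcsp3"]) else None,
        ))
    return recs
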