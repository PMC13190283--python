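"""Family-level feature matrices, insertion-site logos, motif variants.

Outputs are tidy pandas frames with deterministic row/column order so the
TSV writers downstream are byte-stable.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classify import FamilyAssignment
from .orf import OrfReport
from .structure import DomainAnnotation

__all__ = ["feature_matrix", "sequence_logo", "motif_variant_proportions",
           "load_census"]

CENSUS_FILE = "census_v1.tsv"


def load_census() -> pd.DataFrame:
    """Bundled reference census of the study system: lineage, ORF-status
    and query-panel counts, as a (section, category, count) frame."""
    from importlib import resources

    text = resources.files("g2lhe.data").joinpath(CENSUS_FILE).read_text()
    rows = [ln.split("\t") for ln in text.splitlines()
            if ln and not ln.startswith("#")]
    df = pd.DataFrame(rows, columns=["section", "category", "count"])
    df["count"] = df["count"].astype(int)
    return df

FEATURE_COLUMNS = [
    "linker_motif",
    "linker5",
    "branch_point",
    "EBS2",
    "Ia",
    "ICa",
    "IC2",
    "LHE_degenerated",
]


def _feature_present(feature: str, ann: DomainAnnotation, rep: Optional[OrfReport],
                     family_motif: Optional[str]) -> Optional[bool]:
    if feature == "linker_motif":
        return None if family_motif is None else ann.div_dv_linker == family_motif
    if feature == "linker5":
        return ann.linker5_present
    if feature == "branch_point":
        return ann.branch_point_present
    if feature == "EBS2":
        return "EBS2" in ann.ebs_calls
    if feature in ("Ia", "ICa", "IC2"):
        return ann.subfeatures.get(feature)
    if feature == "LHE_degenerated":
        return None if rep is None else rep.status == "degenerated"
    raise KeyError(feature)


def feature_matrix(
    annotations: Mapping[str, DomainAnnotation],
    orf_reports: Mapping[str, OrfReport],
    families: Iterable[FamilyAssignment],
) -> pd.DataFrame:
    """Per-family proportions of the diagnostic features.

    The ``linker_motif`` cell is the proportion of members carrying the
    family's modal DIV-DV linker string. Cells are proportions of members
    with the feature callable (unknowns excluded); ``n`` is family size.
    """
    rows = []
    for fam in sorted(families, key=lambda f: f.family):
        if not fam.members:
            raise ValueError(f"family {fam.family} has no members")
        anns = [annotations[m] for m in fam.members]
        motifs = pd.Series([a.div_dv_linker for a in anns])
        modal = motifs.mode().iloc[0]
        row = {"family": fam.family, "n": len(fam.members)}
        for feat in FEATURE_COLUMNS:
            vals = [
                _feature_present(feat, annotations[m], orf_reports.get(m), modal)
                for m in fam.members
            ]
            known = [v for v in vals if v is not None]
            row[feat] = (sum(known) / len(known)) if known else math.nan
        rows.append(row)
    df = pd.DataFrame(rows).set_index("family")
    return df[["n"] + FEATURE_COLUMNS]


def sequence_logo(
    block: Sequence[str],
    alphabet: str = "nt",
    small_sample_correction: bool = False,
) -> pd.DataFrame:
    """Per-position information content and letter heights.

    Information R = log2(|alphabet|) - H with H the Shannon entropy of the
    observed letter frequencies (gaps excluded from frequencies, recorded
    as occupancy); heights are f * R. Columns with occupancy < 50% are
    flagged, never dropped. The optional small-sample correction
    subtracts (s-1)/(2 ln2 n) as in classic logo tools.
    """
    block = [s.upper() for s in block]
    if len(block) < 2 or len(set(len(s) for s in block)) != 1:
        raise ValueError("need >= 2 equal-length sequences")
    size = 4 if alphabet == "nt" else 20
    rows = []
    for pos in range(len(block[0])):
        col = [s[pos] for s in block]
        letters = [c for c in col if c not in "-.*"]
        occupancy = len(letters) / len(col)
        if letters:
            freq = pd.Series(letters).value_counts(sort=False) / len(letters)
            H = float(-(freq * np.log2(freq)).sum())
            R = math.log2(size) - H
            if small_sample_correction:
                R -= (size - 1) / (2 * math.log(2) * len(letters))
            R = max(R, 0.0)
        else:
            freq, R = pd.Series(dtype=float), 0.0
        for letter in sorted(freq.index):
            rows.append({
                "position": pos + 1,
                "letter": letter,
                "frequency": float(freq[letter]),
                "information": R,
                "height": float(freq[letter]) * R,
                "occupancy": occupancy,
                "low_occupancy": occupancy < 0.5,
            })
        if freq.empty:
            rows.append({"position": pos + 1, "letter": "-", "frequency": 0.0,
                         "information": 0.0, "height": 0.0,
                         "occupancy": occupancy, "low_occupancy": True})
    return pd.DataFrame(rows)


def motif_variant_proportions(
    annotations_by_family: Mapping[str, Sequence[DomainAnnotation]],
    motif_field: str = "div_dv_linker",
    min_fraction: float = 0.01,
) -> dict[str, dict[str, float]]:
    """Exact-string tallies of a linker motif per family, normalized to 1;
    variants rarer than *min_fraction* are pooled as ``other``."""
    out: dict[str, dict[str, float]] = {}
    for family in sorted(annotations_by_family):
        anns = annotations_by_family[family]
        if not anns:
            raise ValueError(f"family {family} has no annotations")
        counts = pd.Series([getattr(a, motif_field) for a in anns]).value_counts()
        props = (counts / counts.sum()).to_dict()
        pooled: dict[str, float] = {}
        for variant in sorted(props):
            if props[variant] < min_fraction:
                pooled["other"] = pooled.get("other", 0.0) + props[variant]
            else:
                pooled[variant] = props[variant]
        out[family] = pooled
    return out
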