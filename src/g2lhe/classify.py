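"""Retention screening, subclass calling, family assignment, hit filtering.

Subclass diagnostics follow the established group II rule sets: IIA1 is
called on the CRGA DII-DIII linker plus a GGA-type DIV-DV linker and a
clean DI 3' strand; the IIB split is UU-type linker without domain Ia
(IIB1) versus AG linker with domain Ia (IIB2); IIC is the single-A linker
with domain IC2 absent. Motif comparisons tolerate one substitution
("or its variants"); presence/absence flags are exact. A call needs at
least two matched diagnostics and no hard conflict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .core_io import IntronRecord
from .structure import DomainAnnotation, motif_mismatches

__all__ = [
    "SubclassCall",
    "FamilyAssignment",
    "validate_intron",
    "classify_subclass",
    "assign_family",
    "filter_homolog_hits",
    "global_identity",
]

log = logging.getLogger(__name__)

#: diagnostic DIV-DV linker motif per subclass (DNA alphabet)
DIV_DV_MOTIF = {"IIA1": "GGA", "IIB1": "TT", "IIB2": "AG", "IIC": "A"}
DII_DIII_MOTIF_IIA1 = "CRGA"
MIN_SCORE = 2


def validate_intron(record: IntronRecord, annotation: DomainAnnotation) -> tuple[bool, list[str]]:
    """Retention filter: a catalytic DV plus a complete six-domain scaffold.

    Merged low-confidence segmentations do not count as a complete
    scaffold. Supporting features (EBS1, boundary motif) are recorded in
    the reasons list when absent but are never grounds for exclusion on
    their own.
    """
    reasons = []
    spans = annotation.domain_spans
    if "DV" not in spans or annotation.confidence.get("DV") == "low_confidence":
        reasons.append("no_DV")
    missing = [d for d in ("DI", "DII", "DIII", "DIV", "DVI") if d not in spans]
    if missing:
        reasons.append("missing_domains:" + ",".join(missing))
    if annotation.confidence.get("segmentation") == "low_confidence":
        reasons.append("merged_segmentation")
    retained = not reasons
    # advisory notes only
    if retained and "EBS1" not in annotation.ebs_calls:
        reasons.append("note:EBS1_absent")
    if retained and annotation.linker5_present is None:
        reasons.append("note:no_boundary_motif")
    return retained, reasons


@dataclass
class SubclassCall:
    subclass: str
    score: int
    rule_trace: list = field(default_factory=list)  # (character, observed, expected, matched)

    def __post_init__(self):
        if self.subclass != "unclassified" and self.score < MIN_SCORE:
            raise ValueError("classified call requires score >= 2")


def _motif_matches(observed: str, motif: str) -> bool:
    mm = motif_mismatches(observed, motif)
    return mm is not None and mm <= 1


def _motif_exact(observed: str, motif: str) -> bool:
    return motif_mismatches(observed, motif) == 0


def classify_subclass(annotation: DomainAnnotation) -> SubclassCall:
    """Rule-based subclass call from linker motifs and subfeature flags.

    Pure function of the annotation: evaluates all four rule sets, scores
    their diagnostics, and returns the unique top scorer with score >= 2
    and no hard conflict. Ties, conflicts everywhere, or weak evidence
    yield ``unclassified``.
    """
    dd = annotation.div_dv_linker
    d23 = annotation.dii_diii_linker
    ia = annotation.subfeatures.get("Ia")
    ic2 = annotation.subfeatures.get("IC2")
    clean3p = annotation.subfeatures.get("no_DI_3p_insertion")

    candidates = []
    for sub in ("IIA1", "IIB1", "IIB2", "IIC"):
        trace = []
        conflict = False
        motif = DIV_DV_MOTIF[sub]
        trace.append(("div_dv_linker", dd, motif, _motif_matches(dd, motif)))
        # hard conflict: the linker is exactly another subclass's motif
        for other, om in DIV_DV_MOTIF.items():
            if other != sub and _motif_exact(dd, om):
                conflict = True
        if sub == "IIA1":
            trace.append(("dii_diii_linker", d23, DII_DIII_MOTIF_IIA1,
                          _motif_matches(d23, DII_DIII_MOTIF_IIA1)))
            trace.append(("no_DI_3p_insertion", clean3p, True, clean3p is True))
        elif sub == "IIB1":
            trace.append(("Ia", ia, False, ia is False))
            if ia is True:
                conflict = True
        elif sub == "IIB2":
            trace.append(("Ia", ia, True, ia is True))
        elif sub == "IIC":
            trace.append(("IC2", ic2, False, ic2 is False))
            if ic2 is True:
                conflict = True
        score = sum(1 for *_x, m in trace if m)
        candidates.append((sub, score, trace, conflict))

    viable = [(s, sc, tr) for s, sc, tr, c in candidates if not c and sc >= MIN_SCORE]
    if not viable:
        return SubclassCall("unclassified", 0,
                            [t for _s, _sc, tr, _c in candidates for t in tr])
    top = max(sc for _s, sc, _t in viable)
    winners = [v for v in viable if v[1] == top]
    if len(winners) > 1:
        return SubclassCall("unclassified", 0,
                            [t for _s, _sc, tr in winners for t in tr])
    sub, score, trace = winners[0]
    return SubclassCall(sub, score, trace)


@dataclass
class FamilyAssignment:
    family: str  # "gene-position"
    members: list
    reference: str = ""


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment, normalized by the longer
    sequence (match +1 / mismatch -1 / gap -2, deterministic)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    matches = 0
    for (as_, ae), (bs, be) in zip(aln.aligned[0], aln.aligned[1]):
        matches += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    return matches / max(len(a), len(b))


def _medoid(records: list[IntronRecord]) -> IntronRecord:
    if len(records) == 1:
        return records[0]
    ordered = sorted(records, key=lambda r: r.id)
    dist = {r.id: 0.0 for r in ordered}
    for i, r1 in enumerate(ordered):
        for r2 in ordered[i + 1 :]:
            d = 1.0 - global_identity(r1.sequence, r2.sequence)
            dist[r1.id] += d
            dist[r2.id] += d
    return min(ordered, key=lambda r: (dist[r.id], r.id))


def assign_family(
    records: Iterable[IntronRecord],
    similarity_threshold: float = 0.60,
) -> list[FamilyAssignment]:
    """Group records into ``gene-position`` families.

    Records sharing (host_gene, insertion_site) form a family; a
    site-unknown record joins the family whose medoid it matches at
    >= *similarity_threshold* global identity (same gene only).
    Site-unknown records matching nothing stay unassigned.
    """
    records = list(records)
    keyed: dict[tuple[str, int], list[IntronRecord]] = {}
    unknown = []
    for r in records:
        if r.insertion_site is None:
            unknown.append(r)
        else:
            keyed.setdefault((r.host_gene, r.insertion_site), []).append(r)

    medoids = {k: _medoid(v) for k, v in keyed.items()}
    for r in unknown:
        best = None
        for k, med in sorted(medoids.items()):
            if r.host_gene and k[0] != r.host_gene:
                continue
            ident = global_identity(r.sequence, med.sequence)
            if ident >= similarity_threshold and (best is None or ident > best[0]):
                best = (ident, k)
        if best is not None:
            keyed[best[1]].append(r)

    out = []
    for (gene, site), members in sorted(keyed.items()):
        out.append(FamilyAssignment(
            family=f"{gene}-{site}",
            members=sorted(m.id for m in members),
        ))
    return out


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def filter_homolog_hits(
    hit_table,
    query_lengths: dict,
    e_cutoff: float = 1e-5,
    min_coverage: float = 0.30,
) -> pd.DataFrame:
    """Filter a 12-column blast-style hit table.

    Keeps rows with evalue <= *e_cutoff* and alignment length / query
    length >= *min_coverage*; deduplicates per (query, subject) keeping
    the best (lowest) evalue. Malformed rows are skipped with a warning
    count. *hit_table* is a path or a DataFrame in outfmt-6 column order.
    """
    if isinstance(hit_table, pd.DataFrame):
        df = hit_table.copy()
        df.columns = BLAST6_COLUMNS[: len(df.columns)]
        skipped = 0
    else:
        rows, skipped = [], 0
        with open(hit_table, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 12:
                    skipped += 1
                    continue
                try:
                    parts[10] = float(parts[10])
                    parts[3] = int(parts[3])
                except ValueError:
                    skipped += 1
                    continue
                rows.append(parts)
        df = pd.DataFrame(rows, columns=BLAST6_COLUMNS)
    if skipped:
        log.warning("filter_homolog_hits: skipped %d malformed rows", skipped)
    if df.empty:
        return df
    df["evalue"] = df["evalue"].astype(float)
    df["length"] = df["length"].astype(int)
    qlen = df["qseqid"].map(query_lengths)
    if qlen.isna().any():
        missing = sorted(df.loc[qlen.isna(), "qseqid"].unique())
        raise ValueError(f"query lengths missing for {missing}")
    keep = (df["evalue"] <= e_cutoff) & (df["length"] / qlen >= min_coverage)
    df = df[keep]
    df = df.sort_values(["qseqid", "sseqid", "evalue"], kind="stable")
    df = df.drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
    return df.reset_index(drop=True)
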