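"""LHE ORF discovery, LAGLIDADG motif scanning, degeneration rubric.

The degeneration rubric mirrors how curators call a dead homing
endonuclease: an in-frame stop between the motif anchors, motif anchors
landing in different reading frames (a frameshift proxy that needs no
alignment), fewer motifs than the family expects, an ORF shorter than
70% of the family's intact median, or a non-acidic residue at the
motif's catalytic column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core_io import IntronRecord
from .structure import DomainAnnotation

__all__ = [
    "OrfReport",
    "FamilyContext",
    "find_orfs",
    "scan_laglidadg",
    "score_degeneration",
    "locate_orf_domain",
    "load_pwm",
    "consensus_self_score",
]

PWM_FILE = "laglidadg_pwm_v1.tsv"
MOTIF_WIDTH = 10
CATALYTIC_COLUMN = 8  # 1-based PWM column holding the acidic residue
DEFAULT_THRESHOLD_FRACTION = 0.60
TRUNCATION_FRACTION = 0.70
START_CODONS = ("ATG", "GTG")


def load_pwm() -> dict[str, np.ndarray]:
    """Load the versioned LAGLIDADG log-odds matrix: residue -> 10 scores."""
    text = resources.files("g2lhe.data").joinpath(PWM_FILE).read_text()
    pwm = {}
    for line in text.splitlines():
        if line.startswith("#") or line.startswith("res"):
            continue
        parts = line.split("\t")
        pwm[parts[0]] = np.array([float(x) for x in parts[1:]])
    return pwm


_PWM_CACHE: Optional[dict] = None


def _pwm() -> dict:
    global _PWM_CACHE
    if _PWM_CACHE is None:
        _PWM_CACHE = load_pwm()
    return _PWM_CACHE


def consensus_self_score() -> float:
    pwm = _pwm()
    return float(sum(max(pwm[aa][i] for aa in pwm) for i in range(MOTIF_WIDTH)))


@dataclass(frozen=True)
class MotifHit:
    position: int  # 1-based aa position in the scanned protein
    score: float
    matched: str

    @property
    def catalytic_residue(self) -> str:
        return self.matched[CATALYTIC_COLUMN - 1]


def scan_laglidadg(protein: str, threshold: Optional[float] = None) -> list[MotifHit]:
    """Non-overlapping LAGLIDADG motif hits, greedy best-first.

    Default threshold is 60% of the consensus self-score. Windows
    containing stops or unknown residues are skipped. Hit order in the
    returned list is by position.
    """
    if len(protein) < MOTIF_WIDTH:
        raise ValueError("protein shorter than the motif window")
    thr = DEFAULT_THRESHOLD_FRACTION * consensus_self_score() if threshold is None else threshold
    pwm = _pwm()
    scored = []
    for i in range(len(protein) - MOTIF_WIDTH + 1):
        window = protein[i : i + MOTIF_WIDTH]
        if any(aa not in pwm for aa in window):
            continue
        s = float(sum(pwm[aa][k] for k, aa in enumerate(window)))
        if s >= thr:
            scored.append(MotifHit(i + 1, s, window))
    scored.sort(key=lambda h: (-h.score, h.position))
    chosen: list[MotifHit] = []
    for h in scored:
        if all(abs(h.position - c.position) >= MOTIF_WIDTH for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.position)
    return chosen


def find_orfs(
    sequence: str,
    table_id: int = 4,
    min_aa: int = 100,
) -> list[tuple[tuple[int, int], int, str]]:
    """Forward-strand ORFs, longest first.

    One ORF per (frame, stop segment): from the first ATG/GTG start to the
    stop codon (span includes the stop; an ORF running off the 3' end
    stops at the last complete codon). Returns
    ``[((start, end) 1-based, frame, protein), ...]``.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[table_id]
    except KeyError:
        raise ValueError(f"unknown translation table {table_id}") from None
    stops = set(table.stop_codons)
    fwd = table.forward_table
    out = []
    n = len(sequence)
    for frame in range(3):
        seg_start = None  # codon index of current ORF start
        i = frame
        codon_idx = 0
        prot: list[str] = []
        while i + 3 <= n:
            codon = sequence[i : i + 3]
            if codon in stops:
                if seg_start is not None and len(prot) >= min_aa:
                    s1 = frame + 3 * seg_start + 1
                    out.append(((s1, i + 3), frame, "".join(prot)))
                seg_start, prot = None, []
            else:
                if seg_start is None and codon in START_CODONS:
                    seg_start = codon_idx
                    prot = ["M"]
                elif seg_start is not None:
                    prot.append(fwd.get(codon, "X"))
            i += 3
            codon_idx += 1
        if seg_start is not None and len(prot) >= min_aa:
            s1 = frame + 3 * seg_start + 1
            out.append(((s1, i), frame, "".join(prot)))
    out.sort(key=lambda o: (-len(o[2]), o[0]))
    return out


@dataclass(frozen=True)
class FamilyContext:
    """Family-level expectations used by the degeneration rubric."""

    expected_motifs: int = 2
    median_intact_aa: Optional[int] = None
    c_anchor: Optional[str] = None  # conserved C-terminal peptide, frame anchor


@dataclass
class OrfReport:
    orf_span: Optional[tuple] = None
    strand_frame: int = 0
    protein: str = ""
    motif_hits: list = field(default_factory=list)
    status: str = "none_found"
    flags: set = field(default_factory=set)
    host_domain: str = "unknown"

    def check_invariants(self) -> None:
        if self.status == "intact_double" and (len(self.motif_hits) < 2 or self.flags):
            raise ValueError("intact_double requires >= 2 motifs and no flags")
        if self.status == "intact_single" and (len(self.motif_hits) != 1 or self.flags):
            raise ValueError("intact_single requires exactly 1 motif and no flags")
        if self.status == "degenerated" and not self.flags:
            raise ValueError("degenerated requires non-empty flags")


def _frame_translations(sequence: str, table_id: int) -> list[str]:
    out = []
    for f in range(3):
        sub = sequence[f : f + 3 * ((len(sequence) - f) // 3)]
        out.append(str(Seq(sub).translate(table=table_id)))
    return out


def _find_anchor(translations: list[str], peptide: str, max_mm: int = 2):
    """Best approximate placement of an aa anchor: (frame, aa_pos1) or None."""
    best = None
    for f, prot in enumerate(translations):
        for i in range(len(prot) - len(peptide) + 1):
            mm = sum(1 for a, b in zip(prot[i : i + len(peptide)], peptide) if a != b)
            if mm <= max_mm and (best is None or mm < best[0]):
                best = (mm, f, i + 1)
    return None if best is None else (best[1], best[2])


def score_degeneration(
    record: IntronRecord,
    annotation: Optional[DomainAnnotation] = None,
    family_context: Optional[FamilyContext] = None,
    table_id: int = 4,
    min_aa: int = 50,
) -> OrfReport:
    """Apply the five-criterion degeneration rubric to one record.

    Motifs are scanned in all three forward frames so anchors survive
    frameshifts; the ORF backing the report is the one containing the
    first motif anchor (longest ORF otherwise).
    """
    ctx = family_context or FamilyContext()
    seq = record.sequence
    trans = _frame_translations(seq, table_id)

    # motif hits per frame, positions projected to nucleotide coordinates
    hits_nt = []  # (nt_start1, frame, MotifHit)
    for f, prot in enumerate(trans):
        if len(prot) < MOTIF_WIDTH:
            continue
        for h in scan_laglidadg(prot):
            hits_nt.append((f + 3 * (h.position - 1) + 1, f, h))
    # non-overlapping across frames, best score first
    hits_nt.sort(key=lambda x: (-x[2].score, x[0]))
    kept = []
    for nt1, f, h in hits_nt:
        if all(abs(nt1 - k[0]) >= 3 * MOTIF_WIDTH for k in kept):
            kept.append((nt1, f, h))
    kept.sort(key=lambda x: x[0])
    anchors = kept[: ctx.expected_motifs]

    orfs = find_orfs(seq, table_id=table_id, min_aa=min_aa)
    orf = None
    if anchors:
        a0 = anchors[0][0]
        for span, f, prot in orfs:
            if span[0] <= a0 <= span[1] and f == anchors[0][1]:
                orf = (span, f, prot)
                break
    if orf is None and orfs:
        orf = orfs[0]

    report = OrfReport()
    report.motif_hits = [h for _nt, _f, h in kept]
    if orf is None and not kept:
        return report  # none_found

    flags = set()
    if len(kept) < ctx.expected_motifs:
        flags.add("motif_loss")

    # frame anchors: the two motifs, or motif + conserved C-terminal block
    frame_anchors = [(nt, f) for nt, f, _h in anchors]
    span_end_nt = None
    if len(anchors) >= 2:
        span_end_nt = anchors[-1][0] + 3 * MOTIF_WIDTH - 1
    elif len(anchors) == 1 and ctx.c_anchor:
        ca = _find_anchor(trans, ctx.c_anchor)
        if ca is not None:
            caf, capos = ca
            ca_nt = caf + 3 * (capos - 1) + 1
            if ca_nt > anchors[0][0]:
                frame_anchors.append((ca_nt, caf))
                span_end_nt = ca_nt + 3 * len(ctx.c_anchor) - 1
    if len(frame_anchors) >= 2 and len({f for _nt, f in frame_anchors}) > 1:
        flags.add("frameshift")

    if anchors and span_end_nt is not None:
        f0 = anchors[0][1]
        aa_lo = (anchors[0][0] - 1 - f0) // 3
        aa_hi = (span_end_nt - f0) // 3
        if "*" in trans[f0][aa_lo:aa_hi]:
            flags.add("premature_stop")

    if orf is not None and ctx.median_intact_aa:
        if len(orf[2]) < TRUNCATION_FRACTION * ctx.median_intact_aa:
            flags.add("truncation")

    for _nt, _f, h in anchors:
        if h.catalytic_residue not in "DE":
            flags.add("catalytic_disruption")

    report.flags = flags
    if orf is not None:
        report.orf_span, report.strand_frame, report.protein = orf
    if flags:
        report.status = "degenerated"
    elif len(kept) >= 2:
        report.status = "intact_double"
    elif len(kept) == 1:
        report.status = "intact_single"
    else:
        report.status = "none_found"
    if annotation is not None and report.orf_span and annotation.domain_spans:
        report.host_domain = locate_orf_domain(report.orf_span, annotation.domain_spans)
    report.check_invariants()
    return report


def locate_orf_domain(orf_span: tuple[int, int], domain_spans: dict) -> str:
    """Domain hosting >= 80% of the ORF span; DI reports as DIB (the ORF
    sits in a DI(B) loop), DII or no qualifying domain reports ``other``."""
    s, e = orf_span
    width = e - s + 1
    for d, (ds, de) in domain_spans.items():
        overlap = max(0, min(e, de) - max(s, ds) + 1)
        if overlap / width >= 0.80:
            return {"DI": "DIB", "DIII": "DIII", "DIV": "DIV"}.get(d, "other")
    return "other"
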