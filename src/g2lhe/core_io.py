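"""Domain types, coordinate conventions and I/O for group II-LHE intron analysis.

Coordinate convention: all user-facing coordinates (insertion sites, domain
spans) are 1-based inclusive, matching the ``gene-position`` family
nomenclature in which e.g. ``cox1-874`` names the reference-gene nucleotide
immediately 5' of the intron. Internal computation is free to use 0-based
offsets but every span that crosses the API boundary is 1-based inclusive.

All sequence logic runs on the DNA alphabet; RNA input (U) is normalized to
T on ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IntronRecord",
    "HostReference",
    "SyntheticTruth",
    "Ambiguous",
    "Unmappable",
    "read_intron_set",
    "write_intron_set",
    "map_insertion_site",
    "revcomp",
    "normalize_seq",
]

LINEAGES = ("green_alga", "fungus", "bacterium", "synthetic")
SUBCLASSES = ("IIA1", "IIB1", "IIB2", "IIC")
DOMAINS = ("DI", "DII", "DIII", "DIV", "DV", "DVI")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson-Crick pairs plus the G.T wobble. Wobble participation is opt-in:
#: operations pass ``wobble=True`` only where the contract explicitly says so.
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = _WC_PAIRS | {("G", "T"), ("T", "G")}


def normalize_seq(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T.

    Raises ``ValueError`` on letters outside {A,C,G,T,U,N}.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal nucleotide letters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def pairs_ok(a: str, b: str, wobble: bool = False) -> bool:
    """True if nucleotides *a* and *b* can pair (antiparallel)."""
    return (a, b) in (_WOBBLE_PAIRS if wobble else _WC_PAIRS)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth annotations attached to generator output.

    Spans are 1-based inclusive within the intron sequence.
    """

    subclass: str
    domain_spans: dict  # {"DI": (start, end), ...} all six domains
    branch_point_pos: Optional[int] = None
    linker5_len: int = 0
    orf_status: str = "none_found"  # intact_double | intact_single | degenerated | none_found
    orf_span: Optional[tuple] = None
    orf_frame: int = 0
    motif_positions: tuple = ()  # 1-based aa positions of LAGLIDADG motifs in the ORF protein
    degeneration_flags: frozenset = frozenset()
    dii_diii_linker: str = ""
    div_dv_linker: str = ""
    ebs_set: frozenset = frozenset()
    ebs_spans: dict = field(default_factory=dict)  # {"EBS1": (start,end), ...}
    orf_domain: str = "unknown"  # DIB | DIII | DIV | other | unknown
    subfeatures: dict = field(default_factory=dict)  # {"Ia": bool, "ICa": ..., "IC2": ...}

    def __post_init__(self):
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown subclass {self.subclass!r}")
        spans = [self.domain_spans[d] for d in DOMAINS if d in self.domain_spans]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError("domain spans must be ordered and non-overlapping")


@dataclass(frozen=True)
class IntronRecord:
    """One intron instance: the intron sequence plus its exon context.

    ``sequence`` is the intron only, 5'->3'.  ``insertion_site`` is the
    1-based position of the host-gene nucleotide immediately 5' of the
    intron, or ``None`` when unknown.
    """

    id: str
    sequence: str
    host_gene: str = ""
    lineage: str = ""
    exon5_flank: str = ""
    exon3_flank: str = ""
    insertion_site: Optional[int] = None
    truth: Optional[SyntheticTruth] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))
        if self.exon5_flank:
            object.__setattr__(self, "exon5_flank", normalize_seq(self.exon5_flank))
        if self.exon3_flank:
            object.__setattr__(self, "exon3_flank", normalize_seq(self.exon3_flank))
        if self.lineage and self.lineage not in LINEAGES:
            raise ValueError(f"record {self.id!r}: unknown lineage {self.lineage!r}")
        if self.insertion_site is not None and self.insertion_site < 1:
            raise ValueError(f"record {self.id!r}: insertion_site must be >= 1")

    def with_(self, **kw) -> "IntronRecord":
        return replace(self, **kw)


@dataclass(frozen=True)
class HostReference:
    """An intron-free reference gene. ``accession_label`` is a label only;
    nothing is ever fetched."""

    gene: str
    sequence: str
    accession_label: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty reference sequence")
        object.__setattr__(self, "sequence", normalize_seq(self.sequence))


class Ambiguous:
    """Sentinel: two near-equal alignments disagree on the coordinate."""

    def __repr__(self):  # pragma: no cover
        return "Ambiguous"


class Unmappable:
    """Sentinel: no alignment reaches the identity floor."""

    def __repr__(self):  # pragma: no cover
        return "Unmappable"


AMBIGUOUS = Ambiguous()
UNMAPPABLE = Unmappable()

SIDECAR_COLUMNS = ("id", "host_gene", "lineage", "insertion_site")


def read_intron_set(
    fasta_path: Union[str, Path],
    sidecar_path: Optional[Union[str, Path]] = None,
) -> list[IntronRecord]:
    """Read intron records from FASTA, optionally joined with a TSV sidecar.

    The sidecar is tab-separated with a header row and columns
    id/host_gene/lineage/insertion_site. Records without a sidecar row get
    an unknown insertion site and empty lineage; sidecar rows without a
    FASTA entry are dropped with a warning.
    """
    entries = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not entries:
        raise ValueError(f"{fasta_path}: no FASTA entries")
    seen: set[str] = set()
    for e in entries:
        if e.id in seen:
            raise ValueError(f"{fasta_path}: duplicate id {e.id!r}")
        seen.add(e.id)

    meta: dict[str, dict] = {}
    if sidecar_path is not None:
        with open(sidecar_path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[: len(SIDECAR_COLUMNS)] != list(SIDECAR_COLUMNS):
                raise ValueError(f"{sidecar_path}: expected columns {SIDECAR_COLUMNS}")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                if row["id"] not in seen:
                    warnings.warn(f"sidecar row {row['id']!r} has no FASTA entry; dropped")
                    continue
                meta[row["id"]] = row

    records = []
    for e in entries:
        row = meta.get(e.id, {})
        site = row.get("insertion_site", "")
        records.append(
            IntronRecord(
                id=e.id,
                sequence=str(e.seq),
                host_gene=row.get("host_gene", ""),
                lineage=row.get("lineage", ""),
                insertion_site=int(site) if site not in ("", "NA", "unknown") else None,
            )
        )
    return records


def write_intron_set(
    records: Iterable[IntronRecord],
    fasta_path: Union[str, Path],
    sidecar_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write records as FASTA plus an optional TSV sidecar (deterministic
    column order, LF line endings)."""
    records = list(records)
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(fasta_path),
        "fasta",
    )
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(SIDECAR_COLUMNS) + "\n")
            for r in records:
                site = "" if r.insertion_site is None else str(r.insertion_site)
                fh.write(f"{r.id}\t{r.host_gene}\t{r.lineage}\t{site}\n")


def _ungapped_scan(flank: str, ref: str) -> list[tuple[int, int]]:
    """All ungapped placements of *flank* on *ref*: (matches, end_pos_1based)."""
    n, m = len(ref), len(flank)
    out = []
    for off in range(n - m + 1):
        matches = sum(1 for a, b in zip(flank, ref[off : off + m]) if a == b)
        out.append((matches, off + m))
    return out


def map_insertion_site(
    exon5_flank: str,
    ref: HostReference,
    min_identity: float = 0.60,
) -> Union[int, Ambiguous, Unmappable]:
    """Map an upstream exon flank onto an intron-free reference gene.

    Returns the 1-based reference coordinate aligned to the *last* flank
    nucleotide — i.e. the nucleotide immediately 5' of the intron, the
    number used in family names like ``cox1-874``.

    An exhaustive ungapped offset scan (scored by matches) is tried first;
    a local affine-gap alignment (match +2 / mismatch -3 / open -5 /
    extend -2) is used only when the best ungapped identity is below 80%.
    Returns ``AMBIGUOUS`` when two placements within one score unit of the
    best disagree on the coordinate, and ``UNMAPPABLE`` when the best
    identity over the flank is below *min_identity*.
    """
    flank = normalize_seq(exon5_flank)
    if len(flank) < 15:
        raise ValueError("flank must be >= 15 nt")
    refseq = ref.sequence
    if len(refseq) <= len(flank):
        raise ValueError("reference must be longer than the flank")

    placements = _ungapped_scan(flank, refseq)
    best_matches = max(m for m, _ in placements)
    best_identity = best_matches / len(flank)

    if best_identity >= 0.80:
        coords = {pos for m, pos in placements if m >= best_matches - 1}
        if len(coords) > 1:
            return AMBIGUOUS
        return coords.pop()

    # gapped rescue: intended for flanks with indels, which still align
    # end to end; short chance local hits (low flank coverage) must not
    # map an unrelated flank, so identity over the flank AND coverage of
    # the flank are both required.
    aln_id, coord, tied, coverage = _gapped_map(flank, refseq)
    if aln_id is not None and aln_id >= min_identity and coverage >= 0.75:
        return AMBIGUOUS if tied else coord
    # no acceptable gapped alignment: the full-coverage ungapped placement
    # still maps when it clears the identity floor
    if best_identity >= min_identity:
        coords = {pos for m, pos in placements if m >= best_matches - 1}
        return AMBIGUOUS if len(coords) > 1 else coords.pop()
    return UNMAPPABLE


def _gapped_map(flank: str, refseq: str):
    """Best local affine-gap placement: (identity over flank, 1-based ref
    coordinate of the flank's last nt, tie flag, flank coverage).

    When the local alignment stops before the flank's last nucleotide the
    coordinate is extrapolated along the diagonal, since the insertion
    site is defined by the last flank position.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    alns = aligner.align(refseq, flank)
    if len(alns) == 0:
        return None, None, False, 0.0
    best = alns[0]
    best_score = best.score
    coords = set()
    for i, aln in enumerate(alns):
        if i > 50:  # degenerate repeat case: cap enumeration
            break
        if aln.score < best_score - 1:
            break
        ref_aln, fl_aln = aln.aligned
        # 0-based end-exclusive == 1-based inclusive; extrapolate to flank end
        coords.add(int(ref_aln[-1][1]) + (len(flank) - int(fl_aln[-1][1])))
    identical = 0
    covered = 0
    for (rs, re_), (fs, fe) in zip(best.aligned[0], best.aligned[1]):
        identical += sum(1 for a, b in zip(refseq[rs:re_], flank[fs:fe]) if a == b)
        covered += fe - fs
    return (identical / len(flank), max(coords), len(coords) > 1,
            covered / len(flank))
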