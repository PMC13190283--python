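"""Six-domain scaffold annotation for group II introns.

Detection order mirrors how a curator works: find the catalytic domain V
stem-loop first (it is the retention criterion), take everything 3' of it
as DVI, partition the upstream region into DI-DIV at the unpaired hub
stretches between stem-loop subtrees, then pull out the diagnostic
characters: the DII-DIII and DIV-DV linker strings, the 5' terminal
linker ahead of the conserved GTGCG boundary, the bulged branch-point
adenosine in DVI, and the EBS loops in DI that mirror the exon IBS sites.

Folding is deterministic base-pair maximization (``fold`` module), not a
thermodynamic prediction; the annotation-guided mode exists so curated or
externally folded structures can be injected instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import fold
from .core_io import DOMAINS, IntronRecord, SyntheticTruth, revcomp, pairs_ok

__all__ = [
    "DomainAnnotation",
    "detect_domain_v",
    "segment_domains",
    "detect_branch_point",
    "detect_terminal_features",
    "detect_ebs",
    "annotate_record",
]

DV_WIDTHS = range(30, 39)  # candidate DV window widths
DV_SEARCH_FRACTION = 0.40  # DV lives in the 3' 40% of the intron
DV_MIN_PAIRED_FRACTION = 0.65
DV_TRIAD_BONUS = 3
MIN_DOMAIN_WIDTH = 12  # smallest credible DII/DIII/DIV stem-loop
MAX_DIV_DV_GAP = 12  # DIV must end within this many nt of the DV window
MAX_LOOP_RUN = 20  # unpaired runs longer than this are hubs, not loops
BOUNDARY5 = "GTGCG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def motif_mismatches(observed: str, motif: str) -> Optional[int]:
    """Substitution count of *observed* against an IUPAC *motif*, or None
    when lengths differ."""
    if len(observed) != len(motif):
        return None
    return sum(o not in IUPAC[m] for o, m in zip(observed, motif.upper()))


@dataclass
class DomainAnnotation:
    """Structural annotation of one intron record.

    Spans are 1-based inclusive in intron coordinates. ``confidence`` maps
    feature names to ``detected`` / ``annotation_supplied`` /
    ``low_confidence``.
    """

    domain_spans: dict = field(default_factory=dict)
    dv_length: int = 0
    dv_paired_fraction: float = 0.0
    dii_diii_linker: str = ""
    div_dv_linker: str = ""
    dv_dvi_linker: str = ""
    linker5_present: Optional[bool] = None
    linker5_len: int = 0
    branch_point_present: Optional[bool] = None
    branch_point_pos: Optional[int] = None
    ebs_calls: dict = field(default_factory=dict)
    subfeatures: dict = field(default_factory=dict)  # Ia/ICa/IC2/... -> True/False/None
    confidence: dict = field(default_factory=dict)

    def validate(self, seq_len: int) -> None:
        spans = [self.domain_spans[d] for d in DOMAINS if d in self.domain_spans]
        prev_end = 0
        for s, e in spans:
            if not (1 <= s <= e <= seq_len):
                raise ValueError("domain span outside sequence bounds")
            if s <= prev_end:
                raise ValueError("domain spans overlap or are out of order")
            prev_end = e


def detect_domain_v(sequence: str) -> Optional[tuple[tuple[int, int], float, bool]]:
    """Locate the catalytic DV stem-loop.

    Scans every window of width 30-38 within the 3' 40% of the sequence.
    A window's score is its maximum nested pair count (minimum helix 3,
    G.T allowed) plus a bonus of 3 when an AGC or CGC trinucleotide lies
    in the first 6 positions. Returns ``((start, end) 1-based,
    paired_fraction, triad_found)`` for the best window — ties broken
    toward the 3'-most start, then the smallest width — or ``None`` when
    the best window's paired fraction is below 0.65.
    """
    n = len(sequence)
    if n < 150:
        raise ValueError("sequence too short for DV detection (< 150 nt)")
    region_start = int(np.floor(n * (1 - DV_SEARCH_FRACTION)))
    region = sequence[region_start:]
    L = len(region)
    wmax = max(DV_WIDTHS)
    B, _H = fold.pair_tables(region, wobble=True, max_span=min(wmax - 1, L - 1))

    best = None  # (score, start0, width, pairs, triad)
    for w in DV_WIDTHS:
        if w > L:
            continue
        for i in range(L - w + 1):
            npairs = int(B[w - 1, i])
            head = region[i : i + 6]
            triad = "AGC" in head or "CGC" in head
            score = npairs + (DV_TRIAD_BONUS if triad else 0)
            key = (score, i, -w)
            if best is None or key > best[0]:
                best = (key, i, w, npairs, triad)
    _key, i, w, npairs, triad = best
    frac = npairs / (w // 2)
    if frac < DV_MIN_PAIRED_FRACTION:
        return None
    start1 = region_start + i + 1
    return (start1, start1 + w - 1), frac, triad


def _mask_orfs(seq: str, min_aa: int = 100) -> str:
    """Replace LHE ORF interiors with N before folding.

    Intron-encoded ORFs are loop insertions; leaving their several hundred
    unstructured nucleotides pairable lets pair maximization glue domains
    together. Only ORFs carrying a LAGLIDADG motif hit are masked — a long
    chance open frame across structural domains must stay foldable. The
    first/last 12 nt of a masked ORF stay visible so the host stem's
    immediate flanks keep their context.
    """
    from .orf import find_orfs, scan_laglidadg, MOTIF_WIDTH

    s = list(seq)
    for (a, b), _f, prot in find_orfs(seq, min_aa=min_aa):
        if len(prot) < MOTIF_WIDTH or not scan_laglidadg(prot):
            continue
        lo, hi = a - 1 + 12, b - 12
        if hi > lo:
            s[lo:hi] = "N" * (hi - lo)
    return "".join(s)


def _anchored_fold(seq: str) -> list[tuple[int, int]]:
    """Anchored heuristic fold used for domain segmentation.

    Long exact reverse-complement stems (>= 10 bp bridging > 60 nt) are
    fixed first as the closing helices of large ORF-hosting domains —
    chance complementarity is negligible at that length, and a global
    pair-maximization would otherwise repartner their strands with the
    abundant chance 3-4-mers elsewhere. Each remaining contiguous segment
    is then folded locally (strict Watson-Crick, locality tie-break) and
    cleansed of low-confidence long-range helices.
    """
    n = len(seq)
    anchors = fold.long_stems(seq, min_len=10, min_span=60)
    blocked = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    for i, j, h in anchors:
        for t in range(h):
            pairs.append((i + t, j - t))
        blocked[i : i + h] = True
        blocked[j - h + 1 : j + 1] = True
    # fold each contiguous unblocked segment on its own
    k = 0
    while k < n:
        if blocked[k]:
            k += 1
            continue
        m = k
        while m < n and not blocked[m]:
            m += 1
        seg = seq[k:m]
        _c, segpairs = fold.max_pairs(seg, wobble=False, locality=True)
        segpairs = fold.filter_helices(segpairs, min_len=6, max_span=35)
        pairs.extend((k + a, k + b) for a, b in segpairs)
        k = m
    return sorted(pairs)


def _linker_between(seq: str, pairs, a_end1: int, b_start1: int) -> str:
    """Unpaired nucleotides strictly between two spans (1-based bounds)."""
    mask = fold.paired_mask(len(seq), pairs)
    return "".join(seq[k] for k in range(a_end1, b_start1 - 1) if not mask[k])


def segment_domains(
    record: IntronRecord,
    dv_span: tuple[int, int],
    mode: str = "de_novo",
    supplied: Optional[SyntheticTruth] = None,
) -> DomainAnnotation:
    """Fill domain spans and linker strings given a DV location.

    ``annotation_guided`` copies spans (and subfeature flags) from
    *supplied* — the record's own truth by default — and only extracts the
    linker/motif strings. ``de_novo`` folds the region upstream of DV and
    cuts it into DI-DIV at the three longest unpaired hub stretches
    between top-level stem-loop subtrees; fewer than four subtrees yields
    a single merged low-confidence span.
    """
    seq = record.sequence
    n = len(seq)
    ann = DomainAnnotation()
    dv_s, dv_e = dv_span
    upstream_pairs = None

    if mode == "annotation_guided":
        src = supplied if supplied is not None else record.truth
        if src is None:
            raise ValueError("annotation_guided mode needs supplied annotations")
        ann.domain_spans = dict(src.domain_spans)
        ann.subfeatures = dict(getattr(src, "subfeatures", {}) or {})
        ann.confidence = {d: "annotation_supplied" for d in ann.domain_spans}
        ann.confidence.update({k: "annotation_supplied" for k in ann.subfeatures})
        n5 = len(record.exon5_flank)
        partner = {"EBS1": (n5 - 5, n5), "EBS2": (n5 - 11, n5 - 6), "EBS3": (1, 1)}
        for name, span in (getattr(src, "ebs_spans", {}) or {}).items():
            ann.ebs_calls[name] = {
                "span": span, "partner_span": partner.get(name), "mismatches": 0,
            }
            ann.confidence[name] = "annotation_supplied"
        dv_s, dv_e = ann.domain_spans["DV"]
    elif mode == "de_novo":
        # fold the region upstream of DV with ORF interiors masked; strict
        # Watson-Crick pairing and a long-range helix filter keep chance
        # complementarity from gluing domains together
        upstream = _mask_orfs(seq[: dv_s - 1])
        pairs = _anchored_fold(upstream)
        upstream_pairs = pairs
        subtrees = fold.top_level_subtrees(pairs)
        # DI starts at the conserved boundary motif when one is found
        lk = detect_terminal_features(record)
        di_start0 = lk[1] if lk[0] is not None else 0
        subtrees = [st for st in subtrees if st[1] > di_start0]
        # DII-DIV are the last three substantial subtrees before DV (they
        # are single compact stem-loops by architecture); DIV must end
        # close to the DV window, everything 5' of DII is the multi-helix
        # DI. Tiny subtrees are chance helices, not domains.
        cands = [st for st in subtrees if st[1] - st[0] + 1 >= MIN_DOMAIN_WIDTH]
        ok = (
            len(cands) >= 4
            and (dv_s - 1) - 1 - cands[-1][1] <= MAX_DIV_DV_GAP
            and cands[-4][1] > di_start0
        )
        if not ok:
            ann.domain_spans = {
                "DI": (di_start0 + 1, dv_s - 1 - len_trailing_unpaired(upstream, pairs)),
            }
            ann.confidence["DI"] = "low_confidence"
            ann.confidence["segmentation"] = "low_confidence"
        else:
            for name, st in zip(("DII", "DIII", "DIV"), cands[-3:]):
                ann.domain_spans[name] = (st[0] + 1, st[1] + 1)
                ann.confidence[name] = "detected"
            ann.domain_spans["DI"] = (di_start0 + 1, cands[-4][1] + 1)
            ann.confidence["DI"] = "detected"
            ann.domain_spans = {
                d: ann.domain_spans[d]
                for d in ("DI", "DII", "DIII", "DIV")
            }
        ann.subfeatures = {"Ia": None, "ICa": None, "IC2": None, "no_DI_3p_insertion": None}
        ann.domain_spans["DV"] = (dv_s, dv_e)
        ann.confidence["DV"] = "detected"
        # DVI = from the first paired position after DV to the 3' end;
        # nothing 3' of DV means no DVI to report
        tail = seq[dv_e:]
        if tail:
            _tp, tpairs = fold.max_pairs(tail, wobble=True)
            dvi_off = tpairs[0][0] if tpairs else 0
            ann.domain_spans["DVI"] = (dv_e + dvi_off + 1, n)
            ann.confidence["DVI"] = "detected"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    # linker strings from the (possibly copied) spans. With a trusted
    # segmentation the inter-domain gap can only pair internally, so the
    # guided mode folds just the gap; de-novo reuses the upstream fold.
    spans = ann.domain_spans
    if "DII" in spans and "DIII" in spans:
        if upstream_pairs is not None:
            ann.dii_diii_linker = _linker_between(
                seq, upstream_pairs, spans["DII"][1], spans["DIII"][0])
        else:
            gap = seq[spans["DII"][1] : spans["DIII"][0] - 1]
            _g, gpairs = fold.max_pairs(gap, wobble=True)
            mask = fold.paired_mask(len(gap), gpairs)
            ann.dii_diii_linker = "".join(
                c for c, m in zip(gap, mask) if not m)
    if "DIV" in spans:
        ann.div_dv_linker = seq[spans["DIV"][1] : spans["DV"][0] - 1]
    if "DVI" in spans:
        ann.dv_dvi_linker = seq[spans["DV"][1] : spans["DVI"][0] - 1]
    ann.dv_length = spans["DV"][1] - spans["DV"][0] + 1
    ann.validate(n)
    return ann


def len_trailing_unpaired(seq: str, pairs) -> int:
    mask = fold.paired_mask(len(seq), pairs)
    k = len(seq)
    while k > 0 and not mask[k - 1]:
        k -= 1
    return len(seq) - k


def detect_branch_point(dvi_sequence: str, dvi_start1: int = 1) -> tuple[bool, Optional[int]]:
    """Branch-point adenosine call on a DVI sequence.

    Folds DVI by pair maximization and reports a bulged adenosine:
    an unpaired A on the 3' strand (after the loop), flanked by paired
    positions on both sides, within 10 nt of the DVI base. The returned
    position is 1-based in intron coordinates via *dvi_start1*.
    """
    if len(dvi_sequence) < 10:
        raise ValueError("DVI span too short (< 10 nt)")
    _n, pairs = fold.max_pairs(dvi_sequence, wobble=True)
    if not pairs:
        return False, None
    mask = fold.paired_mask(len(dvi_sequence), pairs)
    last_paired = max(j for _i, j in pairs)
    # the 3' strand starts at the innermost pair's 3' side; positions
    # inside the terminal loop itself are not bulges
    strand3_start = min(j for _i, j in pairs)
    base_limit_lo = max(strand3_start + 1, last_paired - 10)
    for k in range(last_paired - 1, strand3_start, -1):
        if mask[k] or dvi_sequence[k] != "A":
            continue
        if k < base_limit_lo:
            break
        left_paired = any(mask[t] for t in range(strand3_start, k))
        if left_paired and any(mask[t] for t in range(k + 1, len(dvi_sequence))):
            return True, dvi_start1 + k
    return False, None


def detect_terminal_features(record: IntronRecord) -> tuple[Optional[bool], int]:
    """5' terminal linker call: ``(present or None, length)``.

    Looks for the conserved boundary motif (GTGCG, <= 1 mismatch) within
    the first 60 nt; the linker is whatever precedes it. Ties go to the
    5'-most placement with the fewest mismatches.
    """
    head = record.sequence[:60]
    best = None
    for off in range(len(head) - len(BOUNDARY5) + 1):
        mm = motif_mismatches(head[off : off + len(BOUNDARY5)], BOUNDARY5)
        if mm is not None and mm <= 1:
            if best is None or mm < best[0]:
                best = (mm, off)
                if mm == 0:
                    break
    if best is None:
        return None, 0
    return best[1] > 0, best[1]


def _best_match(query: str, target: str, wobble: bool, max_mm: int) -> Optional[tuple[int, int]]:
    """5'-most placement of revcomp-pairing between *query* and *target*.

    *query* is the exon-side (IBS) segment; a placement matches when
    target[k..] read 3'->5' pairs with query read 5'->3'. Returns
    (offset, mismatches) or None.
    """
    q = query
    m = len(q)
    best = None
    for off in range(len(target) - m + 1):
        window = target[off : off + m]
        mm = sum(0 if pairs_ok(window[m - 1 - t], q[t], wobble) else 1 for t in range(m))
        if mm <= max_mm and (best is None or mm < best[1]):
            best = (off, mm)
            if mm == 0:
                break
    return best


def detect_ebs(record: IntronRecord, annotation: DomainAnnotation) -> dict:
    """EBS1/EBS2/EBS3 calls from exon IBS segments vs unpaired DI loops.

    IBS1 = last 6 nt of the 5' exon flank, IBS2 = the 6 nt before it,
    IBS3 = first nt of the 3' exon flank. EBS1/EBS2 are searched in the
    unpaired loop regions of DI with G.T pairing allowed and <= 1
    mismatch; EBS3 is a single complementary nt restricted to the
    coordination-loop region (the loops in the 3' quarter of DI). Each
    call is ``{"span", "partner_span", "mismatches"}``; absent keys mean
    no match passed.
    """
    if len(record.exon5_flank) < 12:
        raise ValueError("exon5_flank shorter than IBS1+IBS2 (12 nt)")
    if len(record.exon3_flank) < 1:
        raise ValueError("exon3_flank empty (IBS3 undefined)")
    if "DI" not in annotation.domain_spans:
        raise ValueError("DI span unknown")
    seq = record.sequence
    di_s, di_e = annotation.domain_spans["DI"]
    di_seq = _mask_orfs(seq[di_s - 1 : di_e])
    pairs = _anchored_fold(di_seq)
    # loop regions: stretches outside strong stems (>= 5 stacked pairs),
    # enclosed by pairs on both sides. Chance 3-4 bp stacks inside loops
    # must not hide an exon-binding site.
    strong = [p for hx in fold.helices(pairs) if len(hx) >= 5 for p in hx]
    mask = fold.paired_mask(len(di_seq), strong)
    runs = [
        (a, b) for a, b in fold.unpaired_runs(len(di_seq), strong)
        if a > 0 and b < len(di_seq) and b - a <= MAX_LOOP_RUN
    ]

    flank5 = record.exon5_flank
    ibs1 = flank5[-6:]
    ibs2 = flank5[-12:-6]
    ibs3 = record.exon3_flank[0]
    n5 = len(flank5)

    calls: dict[str, dict] = {}

    def search(name: str, ibs_seq: str, partner: tuple[int, int], regions) -> None:
        # perfect strict-WC complements of a full 6-nt site are convincing
        # anywhere in DI; wobble-tolerant 1-mismatch matches only inside
        # unpaired loops. A sub-4-nt site (EBS3) carries no signal on its
        # own, so it is strict-WC and confined to its loop regions.
        best = None
        informative = len(ibs_seq) >= 4
        if informative:
            exact = _best_match(ibs_seq, di_seq, wobble=False, max_mm=0)
            if exact is not None:
                best = (0, exact[0])
        if best is None:
            for a, b in regions:
                if b - a < len(ibs_seq):
                    continue
                hit = _best_match(ibs_seq, di_seq[a:b],
                                  wobble=informative,
                                  max_mm=1 if informative else 0)
                if hit is not None:
                    off, mm = hit
                    if best is None or (mm, a + off) < best:
                        best = (mm, a + off)
        if best is not None:
            mm, off = best
            calls[name] = {
                "span": (di_s + off, di_s + off + len(ibs_seq) - 1),
                "partner_span": partner,
                "mismatches": mm,
            }

    search("EBS1", ibs1, (n5 - 5, n5), runs)
    search("EBS2", ibs2, (n5 - 11, n5 - 6), runs)
    # coordination loop region: 3' quarter of DI
    q3 = len(di_seq) * 3 // 4
    coord = [(max(a, q3), b) for a, b in runs if b > q3]
    search("EBS3", ibs3, (1, 1), coord)
    if "EBS3" in calls and calls["EBS3"]["mismatches"] > 0:
        del calls["EBS3"]  # a single nt either pairs or it does not
    return calls


def annotate_record(record: IntronRecord, mode: str = "de_novo") -> DomainAnnotation:
    """Full annotation pipeline for one record.

    ``de_novo`` works from the raw sequence alone; ``annotation_guided``
    copies domain spans and subfeature flags from the record's truth (or
    raises without one) and computes the remaining characters.
    """
    if mode == "annotation_guided":
        dv_span = record.truth.domain_spans["DV"] if record.truth else None
        if dv_span is None:
            raise ValueError("annotation_guided mode needs record.truth")
        ann = segment_domains(record, dv_span, mode="annotation_guided")
    else:
        hit = detect_domain_v(record.sequence)
        if hit is None:
            ann = DomainAnnotation()
            ann.confidence["DV"] = "low_confidence"
            return ann
        dv_span, frac, triad = hit
        ann = segment_domains(record, dv_span, mode="de_novo")
        ann.dv_paired_fraction = frac
    linker_present, linker_len = detect_terminal_features(record)
    ann.linker5_present, ann.linker5_len = linker_present, linker_len
    ann.confidence["linker5"] = "low_confidence" if linker_present is None else "detected"
    if "DVI" in ann.domain_spans:
        s, e = ann.domain_spans["DVI"]
        if e - s + 1 >= 10:
            bp, bp_pos = detect_branch_point(record.sequence[s - 1 : e], s)
            ann.branch_point_present, ann.branch_point_pos = bp, bp_pos
    if not ann.ebs_calls and record.exon5_flank and record.exon3_flank \
            and "DI" in ann.domain_spans:
        ann.ebs_calls = detect_ebs(record, ann)
    return ann
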