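"""Biogenesis classification: processing-factor dependence, hairpin
placement, and Drosha processing motifs.

Dependence on a processing factor (Dicer, DGCR8, Drosha) is called from
knockdown exclusivity: present in the wild-type (and, when available, the
factor's CLIP reads) but absent upon knockdown. Hairpin support is assessed
on the genomic window spanning ``flank_bp`` on each side of the sRNA with a
purpose-built single-stem maximizer (Watson-Crick and G:U pairs, nested
along one stem, bounded bulges, no multiloops), and the three Drosha
processing signatures are scanned at fixed offsets around the detected
precursor: a CNNC tetramer around 17 nt downstream of the precursor 3' end,
U(-14)/G(-13) upstream of the precursor 5' end, and a UGU/GUG motif in the
apical loop.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, NamedTuple, Optional

import numpy as np

from .config import PipelineConfig
from .datamodel import BiogenesisProfile, HairpinStructure

log = logging.getLogger(__name__)

NEG = -(10**9)

# base codes: A0 C1 G2 T3; pairable = WC or G:U (G:T in DNA alphabet)
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE[_b] = _c
_PAIRABLE = np.zeros((4, 4), dtype=bool)
for _x, _y in [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]:
    _PAIRABLE[_x, _y] = True


def readset_presence(srna: str, read_set, max_mm: int = 0) -> int:
    """Number of reads identical to ``srna`` within ``max_mm`` substitutions.

    ``read_set`` may be a Counter (sequence -> copies) or an iterable of
    read sequences. Only equal-length reads are compared when mismatches
    are allowed (substitutions, no indels).
    """
    counter = read_set if isinstance(read_set, Counter) else Counter(read_set)
    if max_mm == 0:
        return counter.get(srna, 0)
    total = 0
    probe = np.frombuffer(srna.encode(), dtype=np.uint8)
    for seq, n in counter.items():
        if len(seq) != len(probe):
            continue
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if int((arr != probe).sum()) <= max_mm:
            total += n
    return total


def dependence_call(
    wt_count: int,
    kd_count: int,
    clip_count: Optional[int],
    min_wt: int = 5,
    kd_absent_max: int = 0,
) -> str:
    """Knockdown-exclusivity call for one processing factor.

    dependent: expressed in wild type (>= ``min_wt``), absent in knockdown
    (<= ``kd_absent_max``, default exactly 0) and, when a CLIP read set is
    supplied, crosslinked to the factor (>= 1 CLIP read). independent: still
    expressed (>= ``min_wt``) despite the knockdown. Anything else is
    indeterminate. The call is antitone in the knockdown count.
    """
    if wt_count >= min_wt and kd_count <= kd_absent_max and (clip_count is None or clip_count >= 1):
        return "dependent"
    if kd_count >= min_wt:
        return "independent"
    return "indeterminate"


# ---------------------------------------------------------------------------
# hairpin detection


def detect_hairpin(
    window: str,
    min_stem_pairs: int = 16,
    min_loop_nt: int = 3,
    max_bulge_nt: int = 2,
) -> Optional[HairpinStructure]:
    """Best single-stem hairpin in a sequence window, or None.

    Maximizes the number of nested base pairs (Watson-Crick or G:U) along a
    single stem. Unpaired bulge positions between consecutive pairs are
    allowed up to a total of ``max_bulge_nt`` nucleotides over the whole
    stem (summed over both sides) — bounding the total keeps the objective
    a stem finder rather than a longest-complementary-subsequence problem,
    which would fire on nearly any window. The terminal loop must hold at
    least ``min_loop_nt`` unpaired bases; multiloops are excluded by
    construction. Returns None when the maximum falls below
    ``min_stem_pairs``. Ties break toward the shorter precursor, then the
    leftmost one.

    Recurrence over closed structures (outermost pair (i, j), remaining
    bulge budget b; bulge cost of stepping to inner pair (i+di, j-dj) is
    (di-1) + (dj-1)):
        C[b][i, j] = 1 + max( 0 if j-i-1 >= min_loop,
                              max C[b-c][i+di, j-dj] over c <= b )
    evaluated over anti-diagonals with numpy.
    """
    n = len(window)
    if n < 2 * min_stem_pairs + min_loop_nt:
        raise ValueError(
            f"window of {n} nt is too short for {min_stem_pairs} stem pairs "
            f"and a {min_loop_nt} nt loop"
        )
    codes = _CODE[np.frombuffer(window.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("window contains non-ACGT symbols")
    B = max_bulge_nt
    # D[b][s][i] = C with budget b for pair (i, i+s)
    D: list[list[Optional[np.ndarray]]] = [[None] * n for _ in range(B + 1)]
    steps = [
        (di, dj, (di - 1) + (dj - 1))
        for di in range(1, B + 2)
        for dj in range(1, B + 2)
        if (di - 1) + (dj - 1) <= B
    ]
    for s in range(1, n):
        m = n - s
        pair_ok = _PAIRABLE[codes[:m], codes[s:]]
        base = np.full(m, NEG, dtype=np.int64)
        if s - 1 >= min_loop_nt:
            base[:] = 0
        for b in range(B + 1):
            inner = base.copy()
            for di, dj, cost in steps:
                if cost > b:
                    continue
                s2 = s - di - dj
                if s2 < 1:
                    continue
                prev = D[b - cost][s2]
                if prev is None:
                    continue
                seg = prev[di : di + m]
                if len(seg) < m:
                    seg = np.concatenate([seg, np.full(m - len(seg), NEG, dtype=np.int64)])
                np.maximum(inner, seg, out=inner)
            vals = np.where(pair_ok, 1 + np.maximum(inner, NEG), NEG)
            vals = np.where(vals <= 0, NEG, vals)
            D[b][s] = vals
    best = NEG
    best_ij: Optional[tuple[int, int]] = None
    for s in range(1, n):
        vals = D[B][s]
        if vals is None or not len(vals):
            continue
        vmax = int(vals.max())
        if vmax > best:
            best = vmax
            best_ij = (int(np.argmax(vals)), s)
    if best_ij is None or best < min_stem_pairs:
        return None
    i, s = best_ij
    j = i + s
    pairs = _traceback(D, i, j, B, steps)
    outer_i, outer_j = pairs[0]
    inner_i, inner_j = pairs[-1]
    return HairpinStructure(
        precursor=(outer_i, outer_j + 1),
        arm5=(outer_i, inner_i + 1),
        arm3=(inner_j, outer_j + 1),
        loop=(inner_i + 1, inner_j),
        pairs=pairs,
    )


def _traceback(D, i, j, budget, steps) -> list[tuple[int, int]]:
    pairs = [(i, j)]
    ordered = sorted(steps, key=lambda t: (t[2], t[0]))   # smallest bulges first
    while True:
        value = int(D[budget][j - i][i])
        if value == 1:
            return pairs
        target = value - 1
        found = False
        for di, dj, cost in ordered:
            if cost > budget:
                continue
            i2, j2 = i + di, j - dj
            if j2 - i2 < 1:
                continue
            vals = D[budget - cost][j2 - i2]
            if vals is None or i2 >= len(vals):
                continue
            if int(vals[i2]) == target:
                pairs.append((i2, j2))
                i, j, budget = i2, j2, budget - cost
                found = True
                break
        if not found:                              # pragma: no cover
            raise AssertionError("hairpin traceback failed")


def locate_in_stem(
    hairpin: HairpinStructure,
    srna_interval: tuple[int, int],
    stem_tolerance_nt: int = 2,
    window_length: Optional[int] = None,
) -> bool:
    """True iff all but at most ``stem_tolerance_nt`` positions of the sRNA
    lie within a single arm of the hairpin (window coordinates)."""
    s, e = srna_interval
    if s < 0 or e <= s or (window_length is not None and e > window_length):
        raise ValueError(f"sRNA interval ({s},{e}) outside the analyzed window")
    in_arm = 0
    for a0, a1 in (hairpin.arm5, hairpin.arm3):
        overlap = max(0, min(e, a1) - max(s, a0))
        in_arm = max(in_arm, overlap)
    return (e - s) - in_arm <= stem_tolerance_nt


class MotifFlags(NamedTuple):
    cnnc: Optional[bool]
    basal_u: Optional[bool]
    basal_g: Optional[bool]
    basal_ug: Optional[bool]
    apical_ugu: Optional[bool]


def scan_processing_motifs(
    window: str,
    precursor: tuple[int, int],
    loop: tuple[int, int],
    config: PipelineConfig = PipelineConfig(),
) -> MotifFlags:
    """Scan the three Drosha processing signatures around a precursor.

    Offsets follow the published geometry: downstream offset 1 is the first
    base after the precursor 3' end and the CNNC tetramer may start at any
    offset within ``cnnc_center +/- cnnc_tolerance``; upstream offset -1 is
    the base immediately preceding the precursor 5' end, with U expected at
    ``basal_u_pos`` (-14) and G at ``basal_g_pos`` (-13); the apical motif
    is UGU or GUG anywhere in the terminal loop (internally on the DNA
    alphabet: TGT/GTG). Insufficient flank yields None (indeterminate)
    flags rather than an error.
    """
    n = len(window)
    ps, pe = precursor
    ls, le = loop
    if not (0 <= ps < pe <= n and ps <= ls <= le <= pe):
        raise ValueError("precursor/loop intervals inconsistent with window")

    cnnc: Optional[bool] = None
    lo = config.cnnc_center - config.cnnc_tolerance
    hi = config.cnnc_center + config.cnnc_tolerance
    if pe + hi - 1 + 4 <= n:
        cnnc = any(
            window[pe + off - 1] == "C" and window[pe + off + 2] == "C"
            for off in range(lo, hi + 1)
        )
    else:
        log.warning("insufficient downstream flank for CNNC scan; flag indeterminate")

    basal_u: Optional[bool] = None
    basal_g: Optional[bool] = None
    u_idx = ps + config.basal_u_pos
    g_idx = ps + config.basal_g_pos
    if u_idx >= 0:
        basal_u = window[u_idx] == "T"
    if g_idx >= 0:
        basal_g = window[g_idx] == "G"
    if basal_u is None or basal_g is None:
        log.warning("insufficient upstream flank for basal UG scan")
        basal_ug: Optional[bool] = None
    else:
        basal_ug = basal_u and basal_g

    loop_seq = window[ls:le]
    apical = ("TGT" in loop_seq) or ("GTG" in loop_seq)
    return MotifFlags(cnnc, basal_u, basal_g, basal_ug, apical)


# ---------------------------------------------------------------------------
# integrated per-sRNA profile

PERTURBATION_SETS = (
    "dicer_wt", "dicer_kd", "dicer_clip", "trbp_clip",
    "dgcr8_wt", "dgcr8_kd", "dgcr8_clip", "drosha_wt", "drosha_kd",
)


def build_profile(
    srna_id: str,
    srna_seq: str,
    read_sets: Mapping[str, Counter],
    window: Optional[str] = None,
    srna_window_interval: Optional[tuple[int, int]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> BiogenesisProfile:
    """Full biogenesis profile from perturbation read sets plus, when a
    genomic window is supplied, hairpin placement and motif flags."""

    def count(name: str) -> Optional[int]:
        rs = read_sets.get(name)
        return None if rs is None else readset_presence(srna_seq, rs)

    profile = BiogenesisProfile(srna_id=srna_id)
    counts = {name: count(name) for name in PERTURBATION_SETS}
    if counts["dicer_clip"] is not None:
        profile.dicer_clip = counts["dicer_clip"] > 0
    if counts["trbp_clip"] is not None:
        profile.trbp_clip = counts["trbp_clip"] > 0
    min_wt = config.min_reads
    if counts["dicer_wt"] is not None and counts["dicer_kd"] is not None:
        profile.dicer_dependent = dependence_call(
            counts["dicer_wt"], counts["dicer_kd"], counts["dicer_clip"],
            min_wt, config.kd_absent_max,
        )
    if counts["dgcr8_wt"] is not None and counts["dgcr8_kd"] is not None:
        profile.dgcr8_dependent = dependence_call(
            counts["dgcr8_wt"], counts["dgcr8_kd"], counts["dgcr8_clip"],
            min_wt, config.kd_absent_max,
        )
    if counts["drosha_wt"] is not None and counts["drosha_kd"] is not None:
        profile.drosha_dependent = dependence_call(
            counts["drosha_wt"], counts["drosha_kd"], None,
            min_wt, config.kd_absent_max,
        )
    if window is not None:
        hairpin = detect_hairpin(
            window, config.min_stem_pairs, config.min_loop_nt, config.max_bulge_nt
        )
        if hairpin is not None:
            profile.hairpin_found = True
            if srna_window_interval is not None:
                profile.in_stem = locate_in_stem(
                    hairpin, srna_window_interval, config.stem_tolerance_nt, len(window)
                )
            motifs = scan_processing_motifs(window, hairpin.precursor, hairpin.loop, config)
            profile.cnnc = motifs.cnnc
            profile.basal_u = motifs.basal_u
            profile.basal_g = motifs.basal_g
            profile.basal_ug = motifs.basal_ug
            profile.apical_ugu = motifs.apical_ugu
    return profile


def label_from_profile(profile: BiogenesisProfile) -> str:
    """Collapse the three dependence calls into one biogenesis label."""
    if profile.dgcr8_dependent == "dependent" and profile.drosha_dependent == "dependent":
        return "drosha_dgcr8_dependent"
    if profile.dicer_dependent == "dependent":
        return "dicer_only"
    calls = (profile.dicer_dependent, profile.dgcr8_dependent, profile.drosha_dependent)
    if all(c == "independent" for c in calls):
        return "independent"
    return "indeterminate"
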