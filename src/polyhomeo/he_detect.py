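"""Homeologous-exchange (HE) detection from read depth, Hi-C and read pairs.

In a selfing allotetraploid each subgenome is present in two homozygous
copies, so an HE — a reciprocal replacement of one subgenome's segment by its
homeologous partner — produces exactly 4 copies of one segment and 0 of the
other.  The caller segments a depth track into copy states {0, 2, 4} (ratios
to the genome median), pairs reciprocal 0/4 segments across subgenomes by
projecting intervals through contained homeolog gene pairs, and corroborates
candidates with inter-subgenome Hi-C contact enrichment around the
breakpoints and/or discordant read pairs linking them.  Genes unique to the
lost segment (no homeolog inside the duplicated one) are reported as lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_coverage import CoverageTrack
from .ioformats import ContactMatrix, GenomeAnnotation, HomeologMap

__all__ = [
    "CopyStateThresholds",
    "CopyStateSegment",
    "HECandidate",
    "HECall",
    "window_copy_states",
    "segment_states",
    "project_interval",
    "pair_reciprocal_events",
    "contact_enrichment",
    "discordant_support",
    "call_he",
    "genes_lost",
]


@dataclass(frozen=True)
class CopyStateThresholds:
    """Depth-ratio cutpoints mapping r = depth/median to copy states.

    r < zero_max -> 0 copies; two_lo <= r <= two_hi -> 2; r > four_min -> 4;
    anything else is ambiguous and resolved from its neighbours.
    """

    zero_max: float = 0.25
    two_lo: float = 0.5
    two_hi: float = 1.5
    four_min: float = 1.6


@dataclass(frozen=True)
class CopyStateSegment:
    chrom: str
    start: int
    end: int
    state: int  # copies in {0, 2, 4}
    mean_ratio: float
    n_windows: int
    subgenome: str = ""


@dataclass
class HECandidate:
    """A reciprocal 0/4 pairing before evidence scoring."""

    lost: CopyStateSegment
    duplicated: CopyStateSegment
    replacing_subgenome: str
    jaccard: float
    lost_genes: list[str]
    duplicated_genes: list[str]


@dataclass
class HECall:
    accession: str
    lost: CopyStateSegment
    duplicated: CopyStateSegment
    replacing_subgenome: str
    breakpoints_lost: tuple[int, int]
    breakpoints_duplicated: tuple[int, int]
    coverage_score: float  # reciprocity (Jaccard of projected gene sets)
    contact_enrichment: float | None
    discordant_pairs: int | None
    genes_lost: list[str] = field(default_factory=list)


def window_copy_states(
    track: CoverageTrack,
    thresholds: CopyStateThresholds = CopyStateThresholds(),
) -> pd.DataFrame:
    """Per-window copy state from depth ratios against the genome median.

    Ambiguous windows (ratios between the cutpoints) inherit the majority
    state of their nearest classified neighbours on the same chromosome.
    """
    med = track.genome_median
    if med <= 0:
        raise ValueError("genome median depth is zero; all-zero track?")
    df = track.windows.copy()
    r = df["depth"].to_numpy() / med
    state = np.full(len(df), -1, dtype=int)
    state[r < thresholds.zero_max] = 0
    state[(r >= thresholds.two_lo) & (r <= thresholds.two_hi)] = 2
    state[r > thresholds.four_min] = 4
    df["ratio"] = r
    df["state"] = state
    out = []
    for _, grp in df.groupby("chrom", sort=False):
        s = grp["state"].to_numpy().copy()
        s = _resolve_ambiguous(s)
        g = grp.copy()
        g["state"] = s
        out.append(g)
    return pd.concat(out, axis=0)


def _resolve_ambiguous(states: np.ndarray) -> np.ndarray:
    """Fill -1 entries from flanking runs (longer flank wins; left on ties)."""
    s = states.copy()
    known = np.flatnonzero(s >= 0)
    if len(known) == 0:
        raise ValueError("no window could be assigned a copy state")
    i = 0
    n = len(s)
    while i < n:
        if s[i] >= 0:
            i += 1
            continue
        j = i
        while j < n and s[j] < 0:
            j += 1
        left = i - 1
        right = j
        if left < 0:
            fill = s[right]
        elif right >= n:
            fill = s[left]
        else:
            # length of homogeneous run touching each side
            ll = 1
            while left - ll >= 0 and s[left - ll] == s[left]:
                ll += 1
            rl = 1
            while right + rl < n and s[right + rl] == s[right]:
                rl += 1
            fill = s[left] if ll >= rl else s[right]
        s[i:j] = fill
        i = j
    return s


def segment_states(
    states: pd.DataFrame,
    min_run: int = 5,
    chrom_subgenome: dict[str, str] | None = None,
) -> list[CopyStateSegment]:
    """Maximal same-state runs per chromosome; runs < min_run are absorbed.

    A short run is merged into whichever flanking run is longer (left on
    ties), repeatedly until every remaining run reaches ``min_run`` windows
    or a chromosome is a single run.  Segments cover each chromosome.
    """
    segments: list[CopyStateSegment] = []
    for chrom, grp in states.groupby("chrom", sort=False):
        grp = grp.sort_values("start", kind="stable")
        s = grp["state"].to_numpy().copy()
        runs = _runs(s)
        while len(runs) > 1:
            lengths = [b - a for a, b, _ in runs]
            shortest = int(np.argmin(lengths))
            if lengths[shortest] >= min_run:
                break
            a, b, _ = runs[shortest]
            if shortest == 0:
                fill = runs[1][2]
            elif shortest == len(runs) - 1:
                fill = runs[-2][2]
            else:
                left_len = runs[shortest - 1][1] - runs[shortest - 1][0]
                right_len = runs[shortest + 1][1] - runs[shortest + 1][0]
                fill = (
                    runs[shortest - 1][2]
                    if left_len >= right_len
                    else runs[shortest + 1][2]
                )
            s[a:b] = fill
            runs = _runs(s)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        ratios = grp["ratio"].to_numpy()
        for a, b, st in runs:
            segments.append(
                CopyStateSegment(
                    chrom=chrom,
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    state=int(st),
                    mean_ratio=float(ratios[a:b].mean()),
                    n_windows=int(b - a),
                    subgenome=(chrom_subgenome or {}).get(
                        chrom, str(chrom)[:2].upper()
                    ),
                )
            )
    return segments


def _runs(s: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, end, state) half-open runs of identical values."""
    runs = []
    a = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[a]:
            runs.append((a, i, int(s[a])))
            a = i
    return runs


def project_interval(
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    chrom: str,
    start: int,
    end: int,
) -> tuple[str, int, int, list[str]] | None:
    """Project an interval onto the other subgenome via contained gene pairs.

    Returns (partner chromosome, span start, span end, partner gene ids) or
    None when no contained gene has a homeolog (unprojectable).  The partner
    chromosome is the one carrying most partner genes.
    """
    genes = annotation.genes_in(chrom, start, end)
    partner_map = {**hmap.th_to_ar, **hmap.ar_to_th}
    partners = [
        partner_map[g] for g in genes["gene_id"] if g in partner_map
    ]
    if not partners:
        return None
    pg = annotation.genes.set_index("gene_id").loc[partners]
    target_chrom = pg["chrom"].mode().iloc[0]
    on_target = pg[pg["chrom"] == target_chrom]
    return (
        str(target_chrom),
        int(on_target["start"].min()),
        int(on_target["end"].max()),
        list(on_target.index),
    )


def pair_reciprocal_events(
    segments: list[CopyStateSegment],
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    min_jaccard: float = 0.5,
) -> list[HECandidate]:
    """Pair state-0 segments with reciprocal state-4 homeologous segments.

    A candidate requires the lost segment's projected gene set and a
    duplicated segment's gene set to overlap with Jaccard >= ``min_jaccard``.
    A 0-segment whose homeolog stays at state 2 is a plain deletion, not an
    HE.  Segments containing no homeolog gene pair cannot be projected and
    are skipped with a note.
    """
    out: list[HECandidate] = []
    four = [s for s in segments if s.state == 4]
    for lost in (s for s in segments if s.state == 0):
        proj = project_interval(annotation, hmap, lost.chrom, lost.start, lost.end)
        if proj is None:
            warnings.warn(
                f"segment {lost.chrom}:{lost.start}-{lost.end} has no homeolog "
                "pairs; skipped"
            )
            continue
        _, _, _, partner_genes = proj
        partner_set = set(partner_genes)
        lost_genes = list(
            annotation.genes_in(lost.chrom, lost.start, lost.end)["gene_id"]
        )
        for dup in four:
            if dup.subgenome == lost.subgenome:
                continue
            dup_genes = set(
                annotation.genes_in(dup.chrom, dup.start, dup.end)["gene_id"]
            )
            union = partner_set | dup_genes
            if not union:
                continue
            jac = len(partner_set & dup_genes) / len(union)
            if jac >= min_jaccard:
                out.append(
                    HECandidate(
                        lost=lost,
                        duplicated=dup,
                        replacing_subgenome=dup.subgenome,
                        jaccard=jac,
                        lost_genes=lost_genes,
                        duplicated_genes=sorted(dup_genes),
                    )
                )
    return out


def contact_enrichment(
    contacts: ContactMatrix,
    breakpoint_pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    flank: int = 2,
) -> float | None:
    """Trans-contact enrichment around HE breakpoints.

    Mean contact over bin pairs within ``flank`` bins of each breakpoint
    pair, divided by the mean trans contact over all bin pairs of that
    chromosome pair.  Returns None (missing evidence) when the background is
    empty or zero.
    """
    fg: list[float] = []
    bg: list[float] = []
    for (chrom_a, pos_a), (chrom_b, pos_b) in breakpoint_pairs:
        bins_a = contacts.chrom_bins(chrom_a)
        bins_b = contacts.chrom_bins(chrom_b)
        if len(bins_a) == 0 or len(bins_b) == 0:
            continue
        try:
            ba = contacts.bin_of(chrom_a, pos_a)
            bb = contacts.bin_of(chrom_b, pos_b)
        except KeyError:
            continue
        sel_a = bins_a[np.abs(bins_a - ba) <= flank]
        sel_b = bins_b[np.abs(bins_b - bb) <= flank]
        fg.extend(contacts.matrix[np.ix_(sel_a, sel_b)].ravel())
        bg.extend(contacts.matrix[np.ix_(bins_a, bins_b)].ravel())
    if not bg or float(np.mean(bg)) == 0.0:
        warnings.warn("empty or zero trans background; contact evidence missing")
        return None
    return float(np.mean(fg) / np.mean(bg))


def discordant_support(
    pairs: pd.DataFrame,
    breakpoint_pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    window: int = 2000,
) -> int:
    """Count read pairs linking the two subgenomes at the breakpoints.

    ``pairs`` columns: chrom_a, pos_a, chrom_b, pos_b.  A pair supports a
    breakpoint pair when both ends fall within ``window`` bp of the
    respective breakpoints (end order irrelevant).
    """
    if pairs is None or len(pairs) == 0:
        return 0
    count = 0
    for _, p in pairs.iterrows():
        ends = ((p["chrom_a"], p["pos_a"]), (p["chrom_b"], p["pos_b"]))
        for bp_a, bp_b in breakpoint_pairs:
            def near(end, bp):
                return end[0] == bp[0] and abs(end[1] - bp[1]) <= window

            if (near(ends[0], bp_a) and near(ends[1], bp_b)) or (
                near(ends[0], bp_b) and near(ends[1], bp_a)
            ):
                count += 1
                break
    return count


def _breakpoint_pairs(cand: HECandidate) -> list:
    lost, dup = cand.lost, cand.duplicated
    return [
        ((lost.chrom, lost.start), (dup.chrom, dup.start)),
        ((lost.chrom, lost.end), (dup.chrom, dup.end)),
    ]


def call_he(
    candidates: list[HECandidate],
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    contacts: ContactMatrix | None = None,
    discordant: pd.DataFrame | None = None,
    min_contact: float = 2.0,
    min_pairs: int = 3,
    flank: int = 2,
    pair_window: int = 2000,
    accession: str = "",
) -> list[HECall]:
    """Score candidates with Hi-C / read-pair evidence and emit calls.

    A candidate is called when its coverage reciprocity holds (it would not
    be a candidate otherwise) AND contact enrichment >= ``min_contact`` OR
    discordant pair support >= ``min_pairs``.
    """
    calls: list[HECall] = []
    for cand in candidates:
        bps = _breakpoint_pairs(cand)
        enr = (
            contact_enrichment(contacts, bps, flank=flank)
            if contacts is not None
            else None
        )
        sup = (
            discordant_support(discordant, bps, window=pair_window)
            if discordant is not None
            else None
        )
        ok = (enr is not None and enr >= min_contact) or (
            sup is not None and sup >= min_pairs
        )
        if not ok:
            continue
        calls.append(
            HECall(
                accession=accession,
                lost=cand.lost,
                duplicated=cand.duplicated,
                replacing_subgenome=cand.replacing_subgenome,
                breakpoints_lost=(cand.lost.start, cand.lost.end),
                breakpoints_duplicated=(
                    cand.duplicated.start,
                    cand.duplicated.end,
                ),
                coverage_score=cand.jaccard,
                contact_enrichment=enr,
                discordant_pairs=sup,
                genes_lost=genes_lost(cand, annotation, hmap),
            )
        )
    return calls


def genes_lost(
    cand: HECandidate | HECall,
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
) -> list[str]:
    """Genes in the lost segment with no homeolog inside the duplicated one."""
    lost, dup = cand.lost, cand.duplicated
    in_lost = annotation.genes_in(lost.chrom, lost.start, lost.end)["gene_id"]
    dup_genes = set(
        annotation.genes_in(dup.chrom, dup.start, dup.end)["gene_id"]
    )
    partner_map = {**hmap.th_to_ar, **hmap.ar_to_th}
    return [
        g
        for g in in_lost
        if partner_map.get(g) not in dup_genes
    ]
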