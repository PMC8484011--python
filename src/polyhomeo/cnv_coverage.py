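"""Coverage-ratio copy-number estimation and nucleolar-dominance calls.

Collapsed repeats such as the 45S rDNA arrays are represented once in a
reference assembly, so the number of copies in a sequenced individual can be
estimated from the relative increase in sequencing depth over the locus
compared with the genome-wide mean.  The same coverage track later feeds the
homeologous-exchange caller.  This module also implements the flow-cytometry
2C DNA-content formula used to calibrate genome size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "CopyNumberEstimate",
    "DominanceCall",
    "FlowCytometrySample",
    "estimate_copy_number",
    "equalize_consensus_regions",
    "call_nucleolar_dominance",
    "flow_2c_content",
]


@dataclass
class CoverageTrack:
    """Fixed-width window mean depths per chromosome.

    ``windows`` columns: chrom, start, end, depth (0-based half-open).
    The final window of a chromosome may be truncated.
    """

    windows: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "depth"}
        if not req.issubset(self.windows.columns):
            raise ValueError(f"coverage windows need columns {sorted(req)}")
        if (self.windows["depth"] < 0).any():
            raise ValueError("negative depths in coverage track")
        widths = (self.windows["end"] - self.windows["start"]).to_numpy()
        if len(widths) and len(np.unique(widths)) > 1:
            # allow a short terminal window per chromosome, nothing else
            per_chrom = self.windows.groupby("chrom", sort=False)
            for _, grp in per_chrom:
                w = (grp["end"] - grp["start"]).to_numpy()
                if len(np.unique(w[:-1])) > 1:
                    raise ValueError("window width not constant within track")

    @property
    def window_width(self) -> int:
        return int((self.windows["end"] - self.windows["start"]).mode().iloc[0])

    @property
    def genome_mean(self) -> float:
        return float(self.windows["depth"].mean())

    @property
    def genome_median(self) -> float:
        return float(self.windows["depth"].median())

    def locus_mean(self, chrom: str, start: int, end: int) -> float:
        w = self.windows
        sel = w[(w["chrom"] == chrom) & (w["end"] > start) & (w["start"] < end)]
        if sel.empty:
            raise ValueError(f"locus {chrom}:{start}-{end} covered by no window")
        return float(sel["depth"].mean())


@dataclass(frozen=True)
class CopyNumberEstimate:
    locus_id: str
    copies: float
    baseline: float = 1.0
    genome_mean_depth: float = float("nan")
    genome_median_depth: float = float("nan")


@dataclass(frozen=True)
class DominanceCall:
    """Which parental 45S rRNA allele an accession expresses.

    An allele counts as expressed when its log2(CPM) exceeds ``threshold``
    (strictly), the maximum cross-mapping level seen in the ancestral species.
    """

    accession: str
    th_log_cpm: float
    ar_log_cpm: float
    call: str
    threshold: float = 15.0


@dataclass(frozen=True)
class FlowCytometrySample:
    sample_g1_mean: float
    standard_g1_mean: float
    standard_2c_pg: float


def estimate_copy_number(
    track: CoverageTrack,
    locus: tuple[str, int, int],
    baseline: float = 1.0,
    locus_id: str | None = None,
) -> CopyNumberEstimate:
    """Copies = (mean depth over locus / genome-wide mean depth) x baseline.

    ``baseline`` is the copy count the locus has in the reference (1 for a
    collapsed consensus sequence).  The genome-wide normalizer excludes the
    locus windows themselves: the locus under measurement (typically a
    collapsed repeat consensus carried alongside the assembly) must not
    inflate its own reference level.
    """
    chrom, start, end = locus
    w = track.windows
    in_locus = (w["chrom"] == chrom) & (w["end"] > start) & (w["start"] < end)
    background = w.loc[~in_locus, "depth"]
    if background.empty:
        raise ValueError("locus spans the whole track; no background windows")
    gmean = float(background.mean())
    gmedian = float(background.median())
    if gmean <= 0:
        raise ValueError("genome mean depth is zero; copy number undefined")
    lmean = track.locus_mean(chrom, start, end)
    return CopyNumberEstimate(
        locus_id=locus_id or f"{chrom}:{start}-{end}",
        copies=lmean / gmean * baseline,
        baseline=baseline,
        genome_mean_depth=gmean,
        genome_median_depth=gmedian,
    )


def equalize_consensus_regions(hits: pd.DataFrame) -> dict:
    """Truncate two consensus sequences to their best mutual alignment span.

    Comparing depth-derived copy numbers between two consensus sequences is
    only fair over the region they share, so both loci are restricted to the
    best hit's span on the query coordinate system.  ``hits`` rows need
    columns query, subject, pident, qstart, qend, sstart, send and optionally
    aln_len (the gapped alignment length, reported alongside the coordinate
    span rather than guessed to be equal to it).

    Returns a dict with the matched query span, subject span, span length and
    (if available) gapped alignment length.  With no hit at all a warning is
    issued and ``None`` spans are returned so callers can fall back to
    full-length estimates.
    """
    if hits is None or len(hits) == 0:
        warnings.warn(
            "no alignment between consensus sequences; falling back to "
            "full-length loci"
        )
        return {"query_span": None, "subject_span": None,
                "span_length": None, "gapped_length": None}
    best = hits.sort_values(
        ["pident", "qend"], ascending=[False, False], kind="stable"
    ).iloc[0]
    qstart, qend = int(best["qstart"]), int(best["qend"])
    sstart, send = int(best["sstart"]), int(best["send"])
    span = abs(qend - qstart) + 1  # 1-based inclusive alignment coordinates
    gapped = int(best["aln_len"]) if "aln_len" in best.index and pd.notna(
        best.get("aln_len")
    ) else None
    return {
        "query_span": (qstart, qend),
        "subject_span": (min(sstart, send), max(sstart, send)),
        "span_length": span,
        "gapped_length": gapped,
    }


def call_nucleolar_dominance(
    th_log_cpm: float,
    ar_log_cpm: float,
    accession: str = "",
    threshold: float = 15.0,
) -> DominanceCall:
    """Classify 45S rRNA expression as both / th_only / ar_only / neither.

    The comparison is strictly greater-than at the threshold.
    """
    if not (np.isfinite(th_log_cpm) and np.isfinite(ar_log_cpm)):
        raise ValueError("log2(CPM) values must be finite")
    th_on = th_log_cpm > threshold
    ar_on = ar_log_cpm > threshold
    call = {
        (True, True): "both",
        (True, False): "th_only",
        (False, True): "ar_only",
        (False, False): "neither",
    }[(th_on, ar_on)]
    return DominanceCall(accession, th_log_cpm, ar_log_cpm, call, threshold)


def flow_2c_content(s: FlowCytometrySample) -> float:
    """Sample 2C DNA content (pg) from G1 peak means against a standard.

    2C = (sample G1 peak mean / standard G1 peak mean) x standard 2C content.
    """
    if s.standard_g1_mean <= 0:
        raise ValueError("standard G1 peak mean must be positive")
    if s.sample_g1_mean <= 0 or s.standard_2c_pg <= 0:
        raise ValueError("peak means and standard 2C content must be positive")
    return s.sample_g1_mean / s.standard_g1_mean * s.standard_2c_pg
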