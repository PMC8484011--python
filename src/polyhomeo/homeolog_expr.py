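"""Subgenome-aware expression pipeline for an allopolyploid and its ancestors.

The central problem: in an allopolyploid every gene exists as two homeologous
copies, one per subgenome, and short RNA-seq reads can cross-map between
them.  Pure-ancestor samples expose that cross-mapping (any signal they place
on the other subgenome's rows is spurious), which drives both the
cross-mapping gene filter and the leak-rate estimator.  Library-size
normalization is also subgenome-aware: a pure ancestor only transcribes one
subgenome, while the allopolyploid transcribes both, so effective library
sizes are computed per subgenome (TPM totals scaled by TMM factors) and
averaged for allopolyploid samples.

Downstream operations — homeolog log fold changes, expression filtering,
tissue specificity, per-gene Wilcoxon differential expression with BH
correction, PCA and DEG clustering — all work on accession means of
log2(CPM) with a prior count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, rankdata
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

SPECIES = ("thaliana", "arenosa", "suecica_natural", "suecica_synthetic")
#: which subgenomes each species transcribes
SPECIES_SUBGENOMES = {
    "thaliana": ("TH",),
    "arenosa": ("AR",),
    "suecica_natural": ("TH", "AR"),
    "suecica_synthetic": ("TH", "AR"),
}

__all__ = [
    "ExpressionMatrix",
    "NormalizedExpression",
    "HomeologPairStats",
    "filter_cross_mappers",
    "compute_tpm",
    "tmm_factors",
    "effective_library_sizes",
    "log_cpm",
    "normalize",
    "accession_means",
    "expression_filter",
    "homeolog_logfc",
    "tissue_specific_pairs",
    "differential_expression",
    "pca_by_subgenome",
    "cluster_degs",
    "cross_mapping_rate",
]


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with sample metadata and gene lengths.

    ``samples`` is indexed by sample id with columns species, accession,
    replicate and (optionally) tissue; ``gene_subgenome`` maps every gene to
    TH or AR.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame
    gene_subgenome: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.samples["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")
        if not self.gene_subgenome.index.equals(self.counts.index):
            self.gene_subgenome = self.gene_subgenome.reindex(self.counts.index)
        if self.gene_subgenome.isna().any():
            raise ValueError("every gene needs a subgenome label")

    def species_samples(self, species: str) -> list[str]:
        return list(self.samples.index[self.samples["species"] == species])

    def subgenome_genes(self, subgenome: str) -> pd.Index:
        return self.counts.index[self.gene_subgenome == subgenome]


@dataclass
class NormalizedExpression:
    """log2(CPM) with the effective library sizes and TMM factors behind it."""

    log2_cpm: pd.DataFrame
    effective_sizes: pd.Series
    tmm_factors: pd.DataFrame  # subgenome x sample
    prior: float = 1.0

    def __post_init__(self) -> None:
        if (self.effective_sizes <= 0).any():
            raise ValueError("effective library sizes must be positive")
        if not np.isfinite(self.log2_cpm.to_numpy()).all():
            raise ValueError("non-finite log2(CPM)")


@dataclass
class HomeologPairStats:
    """Per-accession replicate-mean log2(AR homeolog / TH homeolog)."""

    per_accession: pd.DataFrame  # pair x accession
    pair_genes: pd.DataFrame  # pair -> th_gene, ar_gene

    @property
    def accession_means(self) -> pd.Series:
        return self.per_accession.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.per_accession.to_numpy().mean())


# ---------------------------------------------------------------------------
# cross-mapping


def filter_cross_mappers(matrix: ExpressionMatrix, prior: float = 0.5) -> pd.Index:
    """Genes to keep after removing likely cross-mapping artefacts.

    For a TH-subgenome gene, reads in pure arenosa samples can only arrive by
    cross-mapping; if log2((thaliana mean + prior) / (arenosa mean + prior))
    is below 0 the wrong species drives the signal and the gene is removed.
    Mirrored for AR-subgenome genes.  Ties (equal means) are kept.
    """
    th_samples = matrix.species_samples("thaliana")
    ar_samples = matrix.species_samples("arenosa")
    if not th_samples or not ar_samples:
        raise ValueError("cross-mapping filter needs pure samples of both ancestors")
    th_mean = matrix.counts[th_samples].mean(axis=1)
    ar_mean = matrix.counts[ar_samples].mean(axis=1)
    ratio = np.log2((th_mean + prior) / (ar_mean + prior))
    is_th = matrix.gene_subgenome == "TH"
    keep = (is_th & (ratio >= 0)) | (~is_th & (-ratio >= 0))
    return matrix.counts.index[keep]


def cross_mapping_rate(matrix: ExpressionMatrix) -> dict[str, float]:
    """Estimate leak rates from pure-ancestor samples.

    In samples of a pure ancestor, all true transcription comes from that
    ancestor's subgenome, so the fraction of counts landing on the other
    subgenome's rows estimates the cross-mapping rate in that direction.
    Returns ``into_th`` (arenosa signal attributed to TH rows) and
    ``into_ar`` (thaliana signal attributed to AR rows).
    """
    out = {}
    for species, wrong_sub, key in (
        ("arenosa", "TH", "into_th"),
        ("thaliana", "AR", "into_ar"),
    ):
        samples = matrix.species_samples(species)
        if not samples:
            raise ValueError(f"no pure {species} samples; leak rate inapplicable")
        sub = matrix.counts[samples]
        total = sub.to_numpy().sum()
        wrong = sub.loc[matrix.subgenome_genes(wrong_sub)].to_numpy().sum()
        out[key] = float(wrong / total) if total > 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# normalization


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6/sample."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"samples with zero counts have undefined TPM: "
            f"{list(counts.columns[zero])}"
        )
    return rate.div(totals, axis=1) * 1e6


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """Standard TMM factor of one sample against the reference.

    Genes zero in either sample drop out; 30% of M-values and 5% of A-values
    are trimmed from each tail; the surviving M-values are averaged with
    inverse-asymptotic-variance weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        # the M ratio is computed as a single log so that exact count ties
        # stay exactly tied (they share average ranks in the trimming)
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0:
        warnings.warn("no genes survive TMM trimming; factor set to 1")
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1")
        return 1.0
    w = 1.0 / v[keep]
    return float(2.0 ** (np.sum(m[keep] * w) / np.sum(w)))


def tmm_factors(
    counts: pd.DataFrame, reference_sample: str | None = None
) -> pd.Series:
    """TMM scaling factor per sample, normalized to geometric mean 1.

    The reference defaults to the sample whose upper-quartile expression
    (library-size scaled) is closest to the mean upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("samples with zero library size")
    if reference_sample is None:
        f75 = counts.div(lib, axis=1).quantile(0.75, axis=0)
        reference_sample = (f75 - f75.mean()).abs().idxmin()
    ref = counts[reference_sample].to_numpy(dtype=float)
    lib_ref = float(lib[reference_sample])
    factors = {}
    for s in counts.columns:
        factors[s] = _tmm_pair(
            counts[s].to_numpy(dtype=float), ref, float(lib[s]), lib_ref
        )
    f = pd.Series(factors)
    return f / np.exp(np.log(f).mean())


def effective_library_sizes(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    gene_subgenome: pd.Series,
) -> tuple[pd.Series, pd.DataFrame]:
    """Subgenome-aware effective library sizes.

    Per subgenome, TMM factors are computed across the samples whose species
    transcribes that subgenome (other samples carry only cross-mapping noise
    there and get factor 1).  A pure-ancestor sample's size is its TPM total
    over its own subgenome times that subgenome's TMM factor; an
    allopolyploid sample's size is the mean of its two TMM-scaled subgenome
    totals.

    Returns (sizes per sample, TMM factor table subgenome x sample).
    """
    gene_subgenome = gene_subgenome.reindex(tpm.index)
    factors = pd.DataFrame(1.0, index=["TH", "AR"], columns=tpm.columns)
    totals = pd.DataFrame(index=["TH", "AR"], columns=tpm.columns, dtype=float)
    for sub in ("TH", "AR"):
        rows = tpm.index[gene_subgenome == sub]
        totals.loc[sub] = tpm.loc[rows].sum(axis=0)
        users = [
            s
            for s in tpm.columns
            if sub in SPECIES_SUBGENOMES[samples.loc[s, "species"]]
        ]
        if len(users) >= 2:
            factors.loc[sub, users] = tmm_factors(tpm.loc[rows, users])
    sizes = {}
    for s in tpm.columns:
        subs = SPECIES_SUBGENOMES[samples.loc[s, "species"]]
        parts = []
        for sub in subs:
            tot = totals.loc[sub, s]
            if tot <= 0:
                warnings.warn(f"sample {s}: zero TPM total on subgenome {sub}")
            parts.append(tot * factors.loc[sub, s])
        sizes[s] = float(np.mean(parts))
    return pd.Series(sizes), factors


def log_cpm(
    counts: pd.DataFrame, sizes: pd.Series, prior: float = 1.0
) -> pd.DataFrame:
    """log2 counts per million with a prior count: log2((c + prior)/size * 1e6)."""
    sizes = sizes.reindex(counts.columns)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return np.log2((counts + prior).div(sizes, axis=1) * 1e6)


def normalize(matrix: ExpressionMatrix, prior: float = 1.0) -> NormalizedExpression:
    """Full normalization: TPM -> per-subgenome TMM -> effective sizes -> log2 CPM."""
    tpm = compute_tpm(matrix.counts, matrix.lengths)
    sizes, factors = effective_library_sizes(
        tpm, matrix.samples, matrix.gene_subgenome
    )
    lcpm = log_cpm(tpm, sizes, prior=prior)
    return NormalizedExpression(lcpm, sizes, factors, prior)


def accession_means(
    values: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate samples to accession means (the analysis unit).

    Returns (gene x accession means, accession metadata with species).
    """
    acc = samples.loc[values.columns, "accession"]
    means = values.T.groupby(acc).mean().T
    meta = (
        samples.loc[values.columns]
        .groupby("accession")
        .agg(species=("species", "first"))
    )
    return means, meta.loc[means.columns]


# ---------------------------------------------------------------------------
# filtering and homeolog statistics


def expression_filter(
    norm: NormalizedExpression,
    samples: pd.DataFrame,
    pairs: pd.DataFrame,
    min_cpm: float = 1.0,
    min_individuals: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Retain homeolog pairs expressed across the species panels.

    A gene is "expressed" in an individual (accession) when its
    replicate-mean CPM exceeds ``min_cpm``.  Each pair member must clear the
    per-species individual counts on the panels where its subgenome is
    native: the TH member in the thaliana panel, the AR member in the
    arenosa panel, and both members in the natural and synthetic
    allopolyploid panels.  Panels absent from the design are skipped with a
    warning.
    """
    if min_individuals is None:
        min_individuals = {
            "thaliana": 3,
            "arenosa": 1,
            "suecica_natural": 3,
            "suecica_synthetic": 1,
        }
    cpm = 2.0 ** norm.log2_cpm
    means, meta = accession_means(cpm, samples)
    expressed = means > min_cpm

    def n_expressed(gene: str, species: str) -> int:
        accs = meta.index[meta["species"] == species]
        return int(expressed.loc[gene, accs].sum())

    panels_present = set(meta["species"])
    for sp in min_individuals:
        if sp not in panels_present:
            warnings.warn(f"panel {sp} absent; its threshold is skipped")

    member_panels = {
        "th": ["thaliana", "suecica_natural", "suecica_synthetic"],
        "ar": ["arenosa", "suecica_natural", "suecica_synthetic"],
    }
    keep = []
    for _, row in pairs.iterrows():
        ok = True
        for member, gene in (("th", row["th_gene"]), ("ar", row["ar_gene"])):
            if gene not in expressed.index:
                ok = False
                break
            for sp in member_panels[member]:
                if sp not in panels_present:
                    continue
                if n_expressed(gene, sp) < min_individuals[sp]:
                    ok = False
                    break
            if not ok:
                break
        keep.append(ok)
    return pairs[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def homeolog_logfc(
    norm: NormalizedExpression,
    samples: pd.DataFrame,
    pairs: pd.DataFrame,
    species: tuple[str, ...] = ("suecica_natural", "suecica_synthetic"),
) -> HomeologPairStats:
    """Per-accession mean log2(AR homeolog / TH homeolog) for each pair.

    Computed on allopolyploid samples (both homeologs transcribed); the
    population summary is the grand mean, which is ~0 when neither subgenome
    dominates expression.  Pairs with a missing homeolog row are skipped.
    """
    cols = samples.index[samples["species"].isin(species)]
    if len(cols) == 0:
        raise ValueError("no samples of the requested species")
    lcpm = norm.log2_cpm[cols]
    present = pairs["th_gene"].isin(lcpm.index) & pairs["ar_gene"].isin(lcpm.index)
    pairs = pairs[present].reset_index(drop=True)
    th = lcpm.loc[pairs["th_gene"]].to_numpy()
    ar = lcpm.loc[pairs["ar_gene"]].to_numpy()
    lfc = pd.DataFrame(ar - th, index=pairs.index, columns=cols)
    acc = samples.loc[cols, "accession"]
    per_acc = lfc.T.groupby(acc).mean().T
    return HomeologPairStats(per_accession=per_acc, pair_genes=pairs)


def tissue_specific_pairs(
    norm: NormalizedExpression,
    samples: pd.DataFrame,
    pairs: pd.DataFrame,
    tissues: tuple[str, str],
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag pair members with |logFC| >= threshold between two tissues.

    Uses accessions sampled in both tissues; a pair is analysed when at least
    one member is flagged.  The threshold is inclusive.
    """
    t1, t2 = tissues
    s1 = samples.index[samples["tissue"] == t1]
    s2 = samples.index[samples["tissue"] == t2]
    acc1 = set(samples.loc[s1, "accession"])
    acc2 = set(samples.loc[s2, "accession"])
    shared = sorted(acc1 & acc2)
    if not shared:
        raise ValueError("no accession sampled in both tissues")
    m1, _ = accession_means(
        norm.log2_cpm[s1], samples.loc[s1]
    )
    m2, _ = accession_means(
        norm.log2_cpm[s2], samples.loc[s2]
    )
    delta = (m1[shared] - m2[shared]).mean(axis=1)
    out = pairs.copy()
    out["th_flagged"] = delta.reindex(pairs["th_gene"]).abs().to_numpy() >= threshold
    out["ar_flagged"] = delta.reindex(pairs["ar_gene"]).abs().to_numpy() >= threshold
    out["analysed"] = out["th_flagged"] | out["ar_flagged"]
    return out


# ---------------------------------------------------------------------------
# differential expression


def _wilcoxon_pvalues(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum per row of a (genes x samples) split.

    Exact null enumeration when both groups have <= 8 observations and the
    row is tie-free; otherwise the normal approximation with tie and
    continuity corrections.  Rows constant across both groups get p = 1.
    """
    n_genes = a.shape[0]
    stats = np.empty(n_genes)
    pvals = np.ones(n_genes)
    combined = np.concatenate([a, b], axis=1)
    constant = np.ptp(combined, axis=1) == 0
    small = a.shape[1] <= 8 and b.shape[1] <= 8
    has_ties = np.array(
        [len(np.unique(combined[i])) < combined.shape[1] for i in range(n_genes)]
    )
    exact_rows = small & ~has_ties & ~constant
    asym_rows = ~exact_rows & ~constant
    if exact_rows.any():
        res = mannwhitneyu(
            a[exact_rows], b[exact_rows], alternative="two-sided",
            method="exact", axis=1,
        )
        stats[exact_rows] = res.statistic
        pvals[exact_rows] = res.pvalue
    if asym_rows.any():
        res = mannwhitneyu(
            a[asym_rows], b[asym_rows], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        stats[asym_rows] = res.statistic
        pvals[asym_rows] = res.pvalue
    if constant.any():
        # U statistic is still defined; p is 1 by convention
        res = mannwhitneyu(
            a[constant], b[constant], alternative="two-sided",
            method="asymptotic", axis=1,
        )
        stats[constant] = res.statistic
        pvals[constant] = 1.0
    return stats, np.clip(pvals, 0.0, 1.0)


def differential_expression(
    values: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum between two accession groups.

    ``values`` holds accession-level log2(CPM) (replicate means).  P-values
    are BH-adjusted across all genes tested; a gene is called differentially
    expressed when q < alpha.  Direction is the sign of the median
    difference (group_a minus group_b).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two accessions")
    a = values[list(group_a)].to_numpy(dtype=float)
    b = values[list(group_b)].to_numpy(dtype=float)
    stats, pvals = _wilcoxon_pvalues(a, b)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    direction = np.sign(np.median(a, axis=1) - np.median(b, axis=1))
    return pd.DataFrame(
        {
            "statistic": stats,
            "p": pvals,
            "q": qvals,
            "direction": direction,
            "significant": qvals < alpha,
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# structure: PCA and clustering


def pca_by_subgenome(
    norm: NormalizedExpression,
    samples: pd.DataFrame,
    gene_subgenome: pd.Series,
    n_components: int = 2,
    sample_subset: list[str] | None = None,
) -> dict[str, dict]:
    """PCA of samples per subgenome on gene-centered log2(CPM).

    Genes are centered but not scaled; components are ordered by explained
    variance and signed so the largest-magnitude gene loading is positive.
    """
    cols = list(sample_subset) if sample_subset is not None else list(
        norm.log2_cpm.columns
    )
    if len(cols) < 3:
        raise ValueError("PCA needs at least three samples")
    gene_subgenome = gene_subgenome.reindex(norm.log2_cpm.index)
    out = {}
    for sub in ("TH", "AR"):
        rows = norm.log2_cpm.index[gene_subgenome == sub]
        x = norm.log2_cpm.loc[rows, cols].T.to_numpy()
        k = min(n_components, x.shape[0] - 1, x.shape[1])
        if k < n_components:
            warnings.warn(f"subgenome {sub}: components truncated to {k}")
        pca = PCA(n_components=k)
        scores = pca.fit_transform(x)
        loadings = pca.components_
        for j in range(k):
            lead = np.argmax(np.abs(loadings[j]))
            if loadings[j, lead] < 0:
                loadings[j] *= -1
                scores[:, j] *= -1
        out[sub] = {
            "scores": pd.DataFrame(
                scores, index=cols, columns=[f"PC{i+1}" for i in range(k)]
            ),
            "explained_variance_ratio": pca.explained_variance_ratio_,
        }
    return out


def cluster_degs(values: pd.DataFrame, k: int = 3) -> pd.Series:
    """Cluster DEG expression profiles: 1-Pearson distance, average linkage.

    The tree is cut at ``k`` clusters.  Labels are canonicalized (ordered by
    each cluster's lexicographically smallest gene id) so the partition is
    stable under row permutation.  Zero-variance genes cannot enter a
    correlation distance and are assigned afterwards to the nearest cluster
    centroid.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(values) < k:
        raise ValueError("fewer genes than clusters")
    x = values.to_numpy(dtype=float)
    variable = np.ptp(x, axis=1) > 0
    labels = pd.Series(index=values.index, dtype=int, name="cluster")
    xv = x[variable]
    idx_v = values.index[variable]
    if len(idx_v) == 0:
        labels[:] = 1
        return labels
    if k == 1 or len(idx_v) == 1:
        raw = np.ones(len(idx_v), dtype=int)
    else:
        corr = np.corrcoef(xv)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        z = linkage(squareform(dist, checks=False), method="average")
        raw = fcluster(z, t=min(k, len(idx_v)), criterion="maxclust")
    # canonical relabelling: order clusters by their smallest member id
    order = sorted(np.unique(raw), key=lambda c: min(idx_v[raw == c]))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels.loc[idx_v] = [remap[c] for c in raw]
    if (~variable).any():
        centroids = {
            remap[old]: xv[raw == old].mean(axis=0) for old in np.unique(raw)
        }
        for gid in values.index[~variable]:
            prof = values.loc[gid].to_numpy(dtype=float)
            nearest = min(
                centroids, key=lambda c: float(np.sum((centroids[c] - prof) ** 2))
            )
            labels.loc[gid] = nearest
    return labels.astype(int)
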