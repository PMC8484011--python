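"""Population dynamics of transposable-element insertions in an allopolyploid.

Works on presence/absence/missing matrices of TE insertion sites across
accession panels (the abstraction produced by population TE callers such as
PoPoolationTE2).  Covers merging of nearby raw calls into sites, classifying
sites as shared with an ancestral panel or private, per-genome insertion
loads, 4n pooling for comparing a selfing tetraploid against an outcrossing
tetraploid ancestor, site-frequency spectra (also for polarized SNPs), family
collapsing and ancestry assignment by identity/coverage rules, and a null
model for the expected ratio of inter-subgenome transposition events:

    E[jumps A->B] / E[jumps B->A] = (N_A * L_B) / (N_B * L_A)

where N is the number of potential source elements in a subgenome and L the
target subgenome's size.  Deviations from this ratio indicate asymmetric
transposon activity between the subgenomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TEInsertionMatrix",
    "SFS",
    "JumpModel",
    "merge_insertions",
    "classify_sharing",
    "genome_load",
    "pool_4n",
    "site_frequencies",
    "compute_sfs",
    "sfs_from_variants",
    "joint_sfs",
    "collapse_families",
    "assign_ancestry",
    "expected_jump_ratio",
    "observed_jump_ratio",
]

MERGE_DIST = 400  # bp; raw calls of one family closer than this are one site


@dataclass
class TEInsertionMatrix:
    """TE insertion sites x accessions with calls in {present, absent, missing}.

    ``sites`` columns: chrom, pos, family, subgenome.  ``calls`` is aligned to
    ``sites`` row-for-row; values are 1.0 (present), 0.0 (absent) or NaN
    (missing: no read coverage to support either call).  Missing cells are
    excluded from all frequency denominators.
    """

    sites: pd.DataFrame
    calls: pd.DataFrame
    panel: str = ""

    def __post_init__(self) -> None:
        req = {"chrom", "pos", "family", "subgenome"}
        if not req.issubset(self.sites.columns):
            raise ValueError(f"sites need columns {sorted(req)}")
        if len(self.sites) != len(self.calls):
            raise ValueError("sites and calls row counts differ")
        if self.sites.duplicated(["chrom", "pos", "family"]).any():
            raise ValueError("duplicate (chrom, pos, family) sites")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
        if not ok.all():
            raise ValueError("calls must be 1, 0 or missing")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class SFS:
    """Site-frequency spectrum: counts per derived-count class 1..n.

    The fixed class (count n) is included; ``counts`` sums to the number of
    sites that entered the spectrum.
    """

    n: int
    counts: pd.Series
    label: str = "TE"

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class JumpModel:
    """Inputs for the inter-subgenome transposition null model."""

    n_th: float
    n_ar: float
    l_th: float
    l_ar: float
    obs_ar_to_th: float | None = None
    obs_th_to_ar: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_th, self.n_ar, self.l_th, self.l_ar) <= 0:
            raise ValueError("source counts and subgenome lengths must be positive")


# ---------------------------------------------------------------------------
# site construction


def _cluster_positions(pos: np.ndarray, dist: int) -> np.ndarray:
    """Single-linkage cluster ids for sorted positions; gap > dist splits."""
    if len(pos) == 0:
        return np.array([], dtype=int)
    breaks = np.diff(pos) > dist
    return np.concatenate([[0], np.cumsum(breaks)])


def merge_insertions(
    raw_calls: pd.DataFrame,
    dist: int = MERGE_DIST,
    subgenome_of: dict[str, str] | None = None,
    panel: str = "",
) -> TEInsertionMatrix:
    """Merge raw per-accession TE calls into a population site matrix.

    Same-family calls within ``dist`` bp are single-linkage merged, first
    within each accession and then across the population; a merged site's
    position is the midpoint of its member positions.  ``raw_calls`` columns:
    accession, chrom, pos, family.  ``subgenome_of`` maps chromosome to
    subgenome label (default: leading two characters of the chromosome name).
    """
    req = {"accession", "chrom", "pos", "family"}
    if not req.issubset(raw_calls.columns):
        raise ValueError(f"raw calls need columns {sorted(req)}")

    # stage 1: within-accession merge
    per_acc: list[tuple[str, str, str, int]] = []  # accession, chrom, family, pos
    for (acc, chrom, fam), grp in raw_calls.groupby(
        ["accession", "chrom", "family"], sort=True
    ):
        pos = np.sort(grp["pos"].to_numpy())
        cl = _cluster_positions(pos, dist)
        for cid in np.unique(cl):
            members = pos[cl == cid]
            per_acc.append((acc, chrom, fam, int((members.min() + members.max()) // 2)))
    stage1 = pd.DataFrame(per_acc, columns=["accession", "chrom", "family", "pos"])
    accessions = sorted(raw_calls["accession"].unique())

    # stage 2: across-population merge
    site_rows = []
    call_rows = []
    for (chrom, fam), grp in stage1.groupby(["chrom", "family"], sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        cl = _cluster_positions(pos, dist)
        for cid in np.unique(cl):
            sub = grp[cl == cid]
            p = int((sub["pos"].min() + sub["pos"].max()) // 2)
            sg = (
                subgenome_of[chrom]
                if subgenome_of is not None
                else str(chrom)[:2].upper()
            )
            site_rows.append({"chrom": chrom, "pos": p, "family": fam, "subgenome": sg})
            present = set(sub["accession"])
            call_rows.append([1.0 if a in present else 0.0 for a in accessions])
    sites = pd.DataFrame(site_rows, columns=["chrom", "pos", "family", "subgenome"])
    calls = pd.DataFrame(call_rows, columns=accessions, dtype=float)
    order = sites.sort_values(["chrom", "pos", "family"], kind="stable").index
    return TEInsertionMatrix(
        sites.loc[order].reset_index(drop=True),
        calls.loc[order].reset_index(drop=True),
        panel=panel,
    )


def classify_sharing(
    poly: TEInsertionMatrix,
    anc: TEInsertionMatrix,
    dist: int = MERGE_DIST,
) -> pd.DataFrame:
    """Classify every site as shared / unique_polyploid / unique_ancestor.

    Sites are matched across the two panels when they carry the same family
    on the same chromosome within ``dist`` bp (nearest-neighbour, each site
    used once).  A site counts as present in a panel when at least one
    accession has a present call.  Both matrices must be on the same
    coordinate system (the polyploid reference).

    Returns one row per matched or unmatched site: chrom, pos, family,
    subgenome, class, poly_row, anc_row (row indices into the respective
    matrices, -1 if absent from that panel).
    """
    common = set(poly.sites["chrom"]) & set(anc.sites["chrom"])
    if len(poly.sites) and len(anc.sites) and not common:
        raise ValueError(
            "no shared chromosomes between panels; coordinate systems differ"
        )

    poly_present = (poly.calls.to_numpy() == 1.0).any(axis=1)
    anc_present = (anc.calls.to_numpy() == 1.0).any(axis=1)

    rows = []
    used_anc: set[int] = set()
    anc_grouped = {
        key: grp for key, grp in anc.sites.groupby(["chrom", "family"], sort=False)
    }
    for pi, site in poly.sites.iterrows():
        if not poly_present[pi]:
            continue
        key = (site["chrom"], site["family"])
        match = -1
        if key in anc_grouped:
            cand = anc_grouped[key]
            dpos = (cand["pos"] - site["pos"]).abs()
            cand = cand[dpos <= dist]
            cand = cand[[i not in used_anc and anc_present[i] for i in cand.index]]
            if len(cand):
                match = int((cand["pos"] - site["pos"]).abs().idxmin())
                used_anc.add(match)
        cls = "shared" if match >= 0 else "unique_polyploid"
        rows.append(
            {
                "chrom": site["chrom"],
                "pos": site["pos"],
                "family": site["family"],
                "subgenome": site["subgenome"],
                "class": cls,
                "poly_row": pi,
                "anc_row": match,
            }
        )
    for ai, site in anc.sites.iterrows():
        if ai in used_anc or not anc_present[ai]:
            continue
        rows.append(
            {
                "chrom": site["chrom"],
                "pos": site["pos"],
                "family": site["family"],
                "subgenome": site["subgenome"],
                "class": "unique_ancestor",
                "poly_row": -1,
                "anc_row": ai,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "family", "subgenome", "class", "poly_row", "anc_row"],
    )


def genome_load(
    matrix: TEInsertionMatrix, site_classes: pd.Series | None = None
) -> pd.DataFrame:
    """Median present-insertion count per accession, split by sharing class.

    ``site_classes`` is aligned to ``matrix.sites`` rows; when omitted all
    sites form a single class "all".  Missing cells never count as present.
    Returns a table with per-class per-accession counts and the class median.
    """
    classes = (
        site_classes
        if site_classes is not None
        else pd.Series(["all"] * matrix.n_sites)
    )
    present = matrix.calls.to_numpy() == 1.0
    out = []
    for cls in pd.unique(classes):
        mask = (classes == cls).to_numpy()
        counts = present[mask].sum(axis=0)
        for acc, cnt in zip(matrix.accessions, counts):
            out.append({"class": cls, "accession": acc, "count": int(cnt)})
    df = pd.DataFrame(out)
    med = df.groupby("class")["count"].median().rename("median_count")
    return df.merge(med, on="class")


def pool_4n(
    matrix: TEInsertionMatrix, k: int = 4, seed: int | np.random.Generator = 0
) -> pd.Series:
    """Pool k randomly chosen accessions into one pseudo-accession.

    Used to compare a selfing allotetraploid panel (each accession one
    haploid-like profile) against an outcrossing autotetraploid ancestor:
    k haploid subgenome profiles are combined by union.  Present if present
    in any chosen accession; absent if absent in all non-missing; missing if
    missing in all.
    """
    if len(matrix.accessions) < k:
        raise ValueError(f"panel has fewer than k={k} accessions")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    chosen = list(rng.choice(matrix.accessions, size=k, replace=False))
    sub = matrix.calls[chosen].to_numpy()
    pooled = np.full(len(sub), np.nan)
    any_present = (sub == 1.0).any(axis=1)
    all_missing = np.isnan(sub).all(axis=1)
    pooled[any_present] = 1.0
    pooled[~any_present & ~all_missing] = 0.0
    return pd.Series(pooled, name="+".join(chosen))


# ---------------------------------------------------------------------------
# site-frequency spectra


def site_frequencies(
    matrix: TEInsertionMatrix, max_missing: float = 0.2
) -> pd.Series:
    """Per-site present frequency among non-missing calls.

    Sites with more than ``max_missing`` missing calls are dropped (NaN-free
    return, indexed by matrix row).
    """
    vals = matrix.calls.to_numpy(dtype=float)
    nonmiss = (~np.isnan(vals)).sum(axis=1)
    present = np.nansum(vals, axis=1)
    n_acc = vals.shape[1]
    keep = (nonmiss >= (1 - max_missing) * n_acc) & (nonmiss > 0)
    freqs = present[keep] / nonmiss[keep]
    return pd.Series(freqs, index=matrix.sites.index[keep])


def site_key_frequencies(
    matrix: TEInsertionMatrix, max_missing: float = 0.2
) -> pd.Series:
    """Like :func:`site_frequencies` but indexed by (chrom, pos, family).

    Useful for aligning sites across panels that share a coordinate system,
    e.g. before :func:`joint_sfs`.
    """
    freqs = site_frequencies(matrix, max_missing=max_missing)
    keys = pd.MultiIndex.from_frame(
        matrix.sites.loc[freqs.index, ["chrom", "pos", "family"]]
    )
    return pd.Series(freqs.to_numpy(), index=keys)


def compute_sfs(
    matrix: TEInsertionMatrix,
    site_mask: pd.Series | np.ndarray | None = None,
    max_missing: float = 0.2,
    label: str = "TE",
) -> SFS:
    """Site-frequency spectrum of present calls, fixed class included.

    Frequencies (present / non-missing) are binned into integer count
    classes 1..n at the panel's modal non-missing denominator n, so that
    sites with a few missing calls still land in comparable classes.  Sites
    with more than ``max_missing`` missing data, or with no present call,
    are excluded.
    """
    if len(matrix.accessions) < 2:
        raise ValueError("need at least two accessions for an SFS")
    freqs = site_frequencies(matrix, max_missing=max_missing)
    if site_mask is not None:
        mask = pd.Series(np.asarray(site_mask), index=matrix.sites.index)
        freqs = freqs[mask.reindex(freqs.index, fill_value=False)]
    vals = matrix.calls.to_numpy(dtype=float)
    nonmiss = pd.Series((~np.isnan(vals)).sum(axis=1), index=matrix.sites.index)
    n_modal = int(nonmiss.loc[freqs.index].mode().iloc[0]) if len(freqs) else len(
        matrix.accessions
    )
    freqs = freqs[freqs > 0]
    if len(freqs) == 0:
        warnings.warn("no segregating or fixed sites entered the SFS")
        counts = pd.Series(0, index=pd.RangeIndex(1, n_modal + 1))
        return SFS(n=n_modal, counts=counts, label=label)
    cls = np.clip(np.rint(freqs.to_numpy() * n_modal).astype(int), 1, n_modal)
    counts = (
        pd.Series(cls).value_counts().reindex(range(1, n_modal + 1), fill_value=0)
    )
    counts.index.name = "count_class"
    return SFS(n=n_modal, counts=counts, label=label)


def sfs_from_variants(
    snps: pd.DataFrame,
    accession_cols: list[str],
    effect: str | None = None,
    max_missing: float = 0.2,
) -> SFS:
    """SFS of derived alleles from a polarized variant table.

    ``snps`` carries 0/1/NaN genotype columns plus ``ref``, ``alt`` and an
    ``ancestral`` outgroup state; the derived allele is the one differing
    from the ancestral state, and sites where the ancestral state matches
    neither allele are unpolarizable and skipped.  ``effect`` optionally
    restricts to one effect class (synonymous / nonsynonymous / other).
    """
    df = snps
    if effect is not None:
        df = df[df["effect"] == effect]
    polarizable = (df["ancestral"] == df["ref"]) | (df["ancestral"] == df["alt"])
    df = df[polarizable]
    if df.empty:
        warnings.warn("no polarizable sites; empty SFS")
        n = len(accession_cols)
        return SFS(n=n, counts=pd.Series(0, index=pd.RangeIndex(1, n + 1)),
                   label=effect or "SNP")
    geno = df[accession_cols].to_numpy(dtype=float)
    # genotype 1 codes the alt allele; flip where alt is ancestral
    flip = (df["ancestral"] == df["alt"]).to_numpy()
    geno[flip] = 1.0 - geno[flip]
    sites = df[["chrom", "pos"]].copy()
    sites["family"] = "SNP"
    sites["subgenome"] = df["chrom"].astype(str).str[:2].str.upper()
    mat = TEInsertionMatrix(
        sites.reset_index(drop=True),
        pd.DataFrame(geno, columns=accession_cols),
        panel="variants",
    )
    return compute_sfs(mat, max_missing=max_missing, label=effect or "SNP")


def joint_sfs(
    anc_freqs: pd.Series,
    poly_freqs: pd.Series,
    bins: int = 10,
    matched_only: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of (ancestor frequency, polyploid frequency) per site.

    The two series are indexed by a shared site key.  With
    ``matched_only=False`` (default) sites seen in only one panel enter with
    frequency 0 in the other; otherwise only the intersection is used.
    Marginals of the returned histogram equal the 1D spectra computed on the
    same site set.
    """
    if matched_only:
        idx = anc_freqs.index.intersection(poly_freqs.index)
        a = anc_freqs.loc[idx]
        p = poly_freqs.loc[idx]
    else:
        idx = anc_freqs.index.union(poly_freqs.index)
        a = anc_freqs.reindex(idx, fill_value=0.0)
        p = poly_freqs.reindex(idx, fill_value=0.0)
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist, xe, ye = np.histogram2d(a.to_numpy(), p.to_numpy(), bins=[edges, edges])
    return hist, xe, ye


# ---------------------------------------------------------------------------
# family collapse and ancestry


def collapse_families(
    hits: pd.DataFrame,
    lengths: dict[str, int],
    id_min: float = 85.0,
    frac_min: float = 0.85,
) -> set[str]:
    """Collapse highly similar consensus sequences; keep one per component.

    Sequences are joined when a pairwise hit exceeds ``id_min`` percent
    identity over more than ``frac_min`` of the query length (both strict).
    Within each connected component the longest sequence is retained (ties
    broken by lexicographic id).
    """
    g = nx.Graph()
    g.add_nodes_from(lengths)
    if hits is not None and len(hits):
        hot = hits[(hits["pident"] > id_min) & (hits["qcov_frac"] > frac_min)]
        for _, h in hot.iterrows():
            if h["query"] != h["subject"]:
                g.add_edge(h["query"], h["subject"])
    reps = set()
    for comp in nx.connected_components(g):
        reps.add(min(comp, key=lambda s: (-lengths.get(s, 0), s)))
    return reps


def assign_ancestry(
    hits: pd.DataFrame,
    genomes: tuple[str, str] = ("TH", "AR"),
    id_min: float = 80.0,
    frac_min: float = 0.80,
) -> str:
    """Assign one family's ancestry from hits against the two ancestral genomes.

    A genome "passes" when any hit against it exceeds ``id_min`` percent
    identity over more than ``frac_min`` of the consensus length.  Exactly one
    pass gives that ancestry; both give "ambiguous"; none "unassigned".
    """
    passes = []
    for gname in genomes:
        sub = hits[hits["subject_genome"] == gname] if len(hits) else hits
        ok = len(sub) > 0 and bool(
            ((sub["pident"] > id_min) & (sub["qcov_frac"] > frac_min)).any()
        )
        passes.append(ok)
    if passes[0] and passes[1]:
        return "ambiguous"
    if passes[0]:
        return genomes[0]
    if passes[1]:
        return genomes[1]
    return "unassigned"


# ---------------------------------------------------------------------------
# inter-subgenome jump null model


def expected_jump_ratio(model: JumpModel) -> float:
    """Expected fold difference of AR->TH over TH->AR jump counts.

    Under equal per-element activity the number of jumps is proportional to
    the number of potential source elements times the size of the target
    subgenome, so the expected fold is (N_AR * L_TH) / (N_TH * L_AR).
    """
    denom = model.n_th * model.l_ar
    if denom == 0:
        raise ZeroDivisionError("zero denominator in jump null model")
    return (model.n_ar * model.l_th) / denom


def observed_jump_ratio(model: JumpModel) -> dict:
    """Observed AR->TH / TH->AR fold and its excess over the null expectation."""
    if model.obs_ar_to_th is None or model.obs_th_to_ar is None:
        raise ValueError("observed jump counts not set on the model")
    if model.obs_ar_to_th <= 0 or model.obs_th_to_ar <= 0:
        warnings.warn("zero observed jump count; ratio undefined")
        return {"observed": float("nan"), "expected": expected_jump_ratio(model),
                "excess": float("nan")}
    observed = model.obs_ar_to_th / model.obs_th_to_ar
    expected = expected_jump_ratio(model)
    return {"observed": observed, "expected": expected,
            "excess": observed / expected}
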