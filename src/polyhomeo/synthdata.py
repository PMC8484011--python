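"""Miniature allopolyploid system with known ground truth.

Emulates the observable structure of a young allotetraploid formed from two
diverged parents (a "TH" and an "AR" subgenome, 5 + 8 chromosomes): 1:1
homeolog pairs, negative-binomial RNA-seq counts with asymmetric
cross-mapping leakage in pure-ancestor samples (~6% of AR-parent signal onto
TH rows, ~1% the other way), population TE insertion matrices with a founder
bottleneck and selection-skewed private insertions, Poisson per-window read
depth with planted reciprocal 4:0 homeologous-exchange segments and
variable-copy rDNA-like arrays, and Hi-C contact matrices with trans spikes
at HE breakpoints.

Everything is a pure function of (parameters, seed): each generator derives
its own RNG sub-stream from the global seed at a fixed offset, so adding one
output never perturbs another.  Counts are modelled directly (cross-mapping
as signal reassignment between homeolog rows), not at the read level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cnv_coverage import CoverageTrack
from .he_detect import project_interval
from .homeolog_expr import SPECIES, ExpressionMatrix
from .ioformats import ContactMatrix, GenomeAnnotation, HomeologMap
from .te_dynamics import TEInsertionMatrix

__all__ = [
    "SynthParams",
    "GroundTruth",
    "HEEvent",
    "generate_reference",
    "default_design",
    "simulate_expression",
    "simulate_te_populations",
    "build_copy_map",
    "simulate_coverage",
    "simulate_contacts",
    "simulate_discordant_pairs",
]

# fixed RNG sub-stream offsets per generator
_STREAM = {"expression": 1, "te": 2, "coverage": 3, "contacts": 4, "pairs": 5}


@dataclass(frozen=True)
class HEEvent:
    """A planted homeologous exchange: the lost segment's coordinates.

    ``lost_subgenome`` drops to 0 copies over chrom:start-end; the
    homeologous segment on the other subgenome rises to 4.
    """

    lost_subgenome: str
    chrom: str
    start: int
    end: int

    @property
    def replacing_subgenome(self) -> str:
        return "AR" if self.lost_subgenome == "TH" else "TH"


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for the synthetic allopolyploid system.

    Defaults mirror the real system where a value is known: 11.6% subgenome
    divergence, 5 + 8 chromosomes, cross-mapping leakage of 6% (AR signal
    onto TH rows) and 1% (TH onto AR), three replicates per accession, and
    panel sizes of 15 natural allopolyploid / 15 TH-parent / 4 AR-parent /
    2 synthetic-hybrid accessions for expression (18 TH-parent and 9
    AR-parent accessions for the DNA TE panels).
    """

    n_genes_per_subgenome: int = 200
    n_chrom_th: int = 5
    n_chrom_ar: int = 8
    divergence: float = 0.116
    leak_th: float = 0.06  # fraction of AR-parent signal landing on TH rows
    leak_ar: float = 0.01  # fraction of TH-parent signal landing on AR rows
    nb_dispersion: float = 0.05
    n_accessions: dict = field(
        default_factory=lambda: {
            "thaliana": 15,
            "arenosa": 4,
            "suecica_natural": 15,
            "suecica_synthetic": 2,
        }
    )
    n_replicates: int = 3
    n_accessions_te: dict = field(
        default_factory=lambda: {"thaliana": 18, "arenosa": 9, "suecica": 15}
    )
    founder_k: int = 4
    te_freq_shape_shared: tuple = (0.5, 0.5)
    te_freq_shape_private: tuple = (0.2, 2.0)
    n_te_shared: int = 150
    n_te_private_poly: int = 150
    n_te_private_anc: int = 100
    n_te_families: int = 30
    te_source_counts: tuple = (334, 667)  # potential sources (TH, AR)
    jump_rate: float = 0.05  # jumps per (source element x target Mb)
    te_missing_rate: float = 0.02
    he_events: tuple = ()
    depth_mean: float = 20.0
    window: int = 5000
    gene_length: int = 2000
    gene_spacing: int = 5000
    chrom_length_th: int | None = None
    chrom_length_ar: int | None = None
    mean_log2_expression: float = 6.0
    sd_log2_expression: float = 1.5
    accession_sd: float = 0.25
    deg_frac: float = 0.0
    deg_logfc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "leak_th", "leak_ar", "deg_frac",
                     "te_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes_per_subgenome", "n_chrom_th", "n_chrom_ar",
                     "n_replicates", "founder_k", "window", "gene_length",
                     "gene_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")
        if self.gene_length > self.gene_spacing:
            raise ValueError("gene_length exceeds gene_spacing")

    def rng(self, stream: str, seed: int | None = None) -> np.random.Generator:
        base = self.seed if seed is None else seed
        return np.random.default_rng([int(base), _STREAM[stream]])


@dataclass
class GroundTruth:
    """Planted truth accompanying each synthetic output."""

    deg: dict | None = None  # subgenome -> set of DEG gene ids
    leak: dict | None = None  # planted cross-mapping rates
    pair_logfc: dict | None = None  # planted homeolog logFC per pair
    copy_map: pd.DataFrame | None = None  # per-window copy state
    he_events: tuple | None = None
    te_classes: pd.Series | None = None  # sharing class per polyploid site
    te_ancestry: dict | None = None  # family -> subgenome of origin
    jumps: dict | None = None  # direction -> count and expectation


# ---------------------------------------------------------------------------
# reference


def generate_reference(params: SynthParams) -> tuple[GenomeAnnotation, HomeologMap]:
    """Deterministic two-subgenome reference with 1:1 homeolog pairs.

    Genes are laid on a regular grid (``gene_spacing`` apart, length
    ``gene_length``), distributed as evenly as possible over the 5 TH and 8
    AR chromosomes; TH gene i is the homeolog partner of AR gene i.
    """
    chroms = []
    genes = []
    pairs = []
    for sub, n_chrom, fixed_len in (
        ("TH", params.n_chrom_th, params.chrom_length_th),
        ("AR", params.n_chrom_ar, params.chrom_length_ar),
    ):
        n_genes = params.n_genes_per_subgenome
        per_chrom = [
            n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0)
            for i in range(n_chrom)
        ]
        gi = 0
        for ci, n_on_chrom in enumerate(per_chrom):
            needed = n_on_chrom * params.gene_spacing
            length = fixed_len if fixed_len is not None else max(
                needed, params.window
            )
            if needed > length:
                raise ValueError(
                    f"{n_on_chrom} genes at spacing {params.gene_spacing} do "
                    f"not fit on a {length} bp chromosome"
                )
            name = f"{sub}{ci + 1}"
            chroms.append({"chrom": name, "length": int(length),
                           "subgenome": sub})
            for j in range(n_on_chrom):
                start = j * params.gene_spacing
                gid = f"{sub}g{gi:04d}"
                genes.append(
                    {
                        "gene_id": gid,
                        "chrom": name,
                        "start": start,
                        "end": start + params.gene_length,
                        "strand": "+" if (gi + j) % 2 == 0 else "-",
                        "subgenome": sub,
                        "partner": f"{'AR' if sub == 'TH' else 'TH'}g{gi:04d}",
                    }
                )
                gi += 1
    annotation = GenomeAnnotation(
        pd.DataFrame(chroms), pd.DataFrame(genes)
    )
    pairs = pd.DataFrame(
        {
            "pair_id": [f"pair{i:04d}" for i in range(params.n_genes_per_subgenome)],
            "th_gene": [f"THg{i:04d}" for i in range(params.n_genes_per_subgenome)],
            "ar_gene": [f"ARg{i:04d}" for i in range(params.n_genes_per_subgenome)],
        }
    )
    return annotation, HomeologMap(pairs)


def subgenome_lengths_mb(annotation: GenomeAnnotation) -> dict[str, float]:
    by = annotation.chromosomes.groupby("subgenome")["length"].sum()
    return {k: v / 1e6 for k, v in by.items()}


# ---------------------------------------------------------------------------
# expression


def default_design(params: SynthParams, tissue: str = "rosette") -> pd.DataFrame:
    """Sample sheet: every accession of every species panel, replicated."""
    prefix = {
        "thaliana": "tha",
        "arenosa": "are",
        "suecica_natural": "sun",
        "suecica_synthetic": "syn",
    }
    rows = []
    for species, n_acc in params.n_accessions.items():
        for a in range(n_acc):
            acc = f"{prefix.get(species, species[:3])}{a:02d}"
            for r in range(1, params.n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{acc}_r{r}_{tissue}",
                        "species": species,
                        "accession": acc,
                        "replicate": r,
                        "tissue": tissue,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Negative-binomial draw with var = m + dispersion * m^2."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_expression(
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    design: pd.DataFrame | None,
    params: SynthParams,
    pair_logfc: dict[str, float] | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Negative-binomial counts for every sample in the design.

    Pure-ancestor samples transcribe only their own subgenome, but a leak
    fraction of every gene's signal is reassigned to the homeolog's row
    (``leak_th`` of AR-parent signal onto TH rows, ``leak_ar`` of TH-parent
    signal onto AR rows), emulating cross-mapping.  Allopolyploid samples
    express both rows with no leak.  Optional planted effects: per-pair
    homeolog log fold changes (``pair_logfc``) and differential expression
    in natural allopolyploid accessions (``deg_frac`` of genes per subgenome
    shifted by ``deg_logfc``), both recorded in the ground truth.
    """
    if design is None:
        design = default_design(params)
    bad = set(design["species"]) - set(SPECIES)
    if bad:
        raise ValueError(f"unknown species in design: {sorted(bad)}")
    rng = params.rng("expression")

    pairs = hmap.pairs
    n_pairs = len(pairs)
    base = 2.0 ** rng.normal(
        params.mean_log2_expression, params.sd_log2_expression, size=n_pairs
    )
    lfc = np.zeros(n_pairs)
    if pair_logfc:
        idx = {p: i for i, p in enumerate(pairs["pair_id"])}
        for pid, v in pair_logfc.items():
            lfc[idx[pid]] = v
    mu_th = base
    mu_ar = base * 2.0 ** lfc

    genes = list(pairs["th_gene"]) + list(pairs["ar_gene"])
    gene_subgenome = pd.Series(
        ["TH"] * n_pairs + ["AR"] * n_pairs, index=genes
    )
    lengths = (
        annotation.genes.set_index("gene_id")
        .loc[genes, "end"]
        .sub(annotation.genes.set_index("gene_id").loc[genes, "start"])
    )

    # planted DEGs: expression shift in natural allopolyploid accessions
    deg: dict[str, set] = {"TH": set(), "AR": set()}
    deg_mult_th = np.ones(n_pairs)
    deg_mult_ar = np.ones(n_pairs)
    if params.deg_frac > 0:
        n_deg = int(round(params.deg_frac * n_pairs))
        for sub, mult in (("TH", deg_mult_th), ("AR", deg_mult_ar)):
            chosen = rng.choice(n_pairs, size=n_deg, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_deg)
            mult[chosen] = 2.0 ** (signs * params.deg_logfc)
            col = "th_gene" if sub == "TH" else "ar_gene"
            deg[sub] = set(pairs[col].iloc[chosen])

    # accession-level biological effects (shared by replicates)
    accessions = design["accession"].unique()
    acc_effect = {
        acc: 2.0 ** rng.normal(0.0, params.accession_sd, size=2 * n_pairs)
        for acc in accessions
    }

    counts = np.zeros((2 * n_pairs, len(design)), dtype=int)
    for si, (sample, row) in enumerate(design.iterrows()):
        species = row["species"]
        eff = acc_effect[row["accession"]]
        th = np.zeros(n_pairs)
        ar = np.zeros(n_pairs)
        if species == "thaliana":
            th = mu_th * (1.0 - params.leak_ar)
            ar = mu_th * params.leak_ar
        elif species == "arenosa":
            ar = mu_ar * (1.0 - params.leak_th)
            th = mu_ar * params.leak_th
        else:
            th = mu_th.copy()
            ar = mu_ar.copy()
            if species == "suecica_natural":
                th = th * deg_mult_th
                ar = ar * deg_mult_ar
        mean = np.concatenate([th, ar]) * eff
        counts[:, si] = _nb_draw(rng, mean, params.nb_dispersion)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design.index),
        lengths=lengths,
        samples=design,
        gene_subgenome=gene_subgenome,
    )
    truth = GroundTruth(
        deg=deg,
        leak={"into_th": params.leak_th, "into_ar": params.leak_ar},
        pair_logfc=dict(zip(pairs["pair_id"], lfc)),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# TE populations


def simulate_te_populations(
    annotation: GenomeAnnotation,
    params: SynthParams,
    subgenome: str = "TH",
    seed: int | None = None,
) -> tuple[TEInsertionMatrix, TEInsertionMatrix, GroundTruth]:
    """Ancestor and polyploid TE insertion panels on one subgenome.

    Shared sites carry ancestral frequencies Beta(0.5, 0.5); the polyploid's
    frequency at a shared site is a binomial resample of ``founder_k``
    ancestral draws (the founder bottleneck, pushing intermediate
    frequencies toward loss or fixation).  Private insertions on either side
    get Beta(0.2, 2) frequencies (skewed to rare, emulating purifying
    selection).  Inter-subgenome jump sites arrive at a rate proportional to
    the other subgenome's source-element count times this subgenome's length
    and are private to the polyploid.
    """
    if subgenome not in ("TH", "AR"):
        raise ValueError("subgenome must be TH or AR")
    rng = params.rng("te", seed)
    anc_species = "thaliana" if subgenome == "TH" else "arenosa"
    n_anc = params.n_accessions_te[anc_species]
    n_poly = params.n_accessions_te["suecica"]
    if params.founder_k > n_anc:
        raise ValueError("founder_k exceeds the ancestor panel size")

    lengths = subgenome_lengths_mb(annotation)
    l_target = lengths.get(subgenome, 0.0)
    if l_target <= 0:
        raise ValueError(f"zero target length for subgenome {subgenome}")
    n_th_src, n_ar_src = params.te_source_counts
    n_source_other = n_ar_src if subgenome == "TH" else n_th_src
    expected_jumps = params.jump_rate * n_source_other * l_target
    n_jumps = int(rng.poisson(expected_jumps))

    chroms = annotation.chromosomes[
        annotation.chromosomes["subgenome"] == subgenome
    ]
    # candidate positions on a 500 bp grid (> merge distance), so distinct
    # sites never collapse into one another
    grid = [
        (row["chrom"], pos)
        for _, row in chroms.iterrows()
        for pos in range(500, int(row["length"]), 500)
    ]
    n_total = (
        params.n_te_shared + params.n_te_private_poly + params.n_te_private_anc
        + n_jumps
    )
    if n_total > len(grid):
        raise ValueError(
            f"{n_total} TE sites requested but only {len(grid)} grid positions"
        )
    chosen = rng.choice(len(grid), size=n_total, replace=False)
    positions = [grid[i] for i in chosen]

    own_fams = [f"fam_{subgenome}_{i:02d}" for i in range(params.n_te_families)]
    other = "AR" if subgenome == "TH" else "TH"
    other_fams = [f"fam_{other}_{i:02d}" for i in range(params.n_te_families)]
    ancestry = {f: subgenome for f in own_fams}
    ancestry.update({f: other for f in other_fams})

    a_sh, b_sh = params.te_freq_shape_shared
    a_pr, b_pr = params.te_freq_shape_private

    site_rows = []
    anc_calls = []
    poly_calls = []
    classes = []
    cursor = 0

    def add_site(chrom, pos, fam, p_anc, p_poly, cls):
        site_rows.append(
            {"chrom": chrom, "pos": pos, "family": fam, "subgenome": subgenome}
        )
        anc_calls.append(
            rng.binomial(1, p_anc, size=n_anc).astype(float)
            if p_anc is not None
            else np.zeros(n_anc)
        )
        poly_calls.append(
            rng.binomial(1, p_poly, size=n_poly).astype(float)
            if p_poly is not None
            else np.zeros(n_poly)
        )
        classes.append(cls)

    for _ in range(params.n_te_shared):
        chrom, pos = positions[cursor]
        cursor += 1
        p = rng.beta(a_sh, b_sh)
        p_poly = rng.binomial(params.founder_k, p) / params.founder_k
        add_site(chrom, pos, rng.choice(own_fams), p, p_poly, "shared")
    for _ in range(params.n_te_private_poly):
        chrom, pos = positions[cursor]
        cursor += 1
        add_site(chrom, pos, rng.choice(own_fams), None,
                 rng.beta(a_pr, b_pr), "unique_polyploid")
    for _ in range(params.n_te_private_anc):
        chrom, pos = positions[cursor]
        cursor += 1
        add_site(chrom, pos, rng.choice(own_fams), rng.beta(a_pr, b_pr),
                 None, "unique_ancestor")
    for _ in range(n_jumps):
        chrom, pos = positions[cursor]
        cursor += 1
        add_site(chrom, pos, rng.choice(other_fams), None,
                 rng.beta(a_pr, b_pr), "jump")

    sites = pd.DataFrame(site_rows)
    anc_cols = [f"{anc_species[:3]}{i:02d}" for i in range(n_anc)]
    poly_cols = [f"sue{i:02d}" for i in range(n_poly)]
    anc = pd.DataFrame(np.array(anc_calls), columns=anc_cols)
    poly = pd.DataFrame(np.array(poly_calls), columns=poly_cols)

    if params.te_missing_rate > 0:
        for df in (anc, poly):
            mask = rng.random(df.shape) < params.te_missing_rate
            df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns),
                    inplace=True)

    # panels only carry sites observed in them (>=1 present call);
    # the truth keeps every planted site
    anc_seen = (anc == 1.0).any(axis=1)
    poly_seen = (poly == 1.0).any(axis=1)
    anc_matrix = TEInsertionMatrix(
        sites[anc_seen].reset_index(drop=True),
        anc[anc_seen].reset_index(drop=True),
        panel=anc_species,
    )
    poly_matrix = TEInsertionMatrix(
        sites[poly_seen].reset_index(drop=True),
        poly[poly_seen].reset_index(drop=True),
        panel="suecica",
    )
    truth = GroundTruth(
        te_classes=pd.Series(classes, index=pd.MultiIndex.from_frame(
            sites[["chrom", "pos", "family"]]
        )),
        te_ancestry=ancestry,
        jumps={
            "into_" + subgenome.lower(): n_jumps,
            "expected_into_" + subgenome.lower(): expected_jumps,
        },
    )
    return anc_matrix, poly_matrix, truth


# ---------------------------------------------------------------------------
# coverage


def build_copy_map(
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    window: int,
    he_events: tuple[HEEvent, ...] = (),
    rdna_loci: dict[tuple[str, int, int], float] | None = None,
) -> pd.DataFrame:
    """Per-window copy states: baseline 2, with HE 0/4 and rDNA multipliers.

    For each HE event the lost segment's windows go to 0 copies and the
    projected homeologous segment's windows to 4.  ``rdna_loci`` maps a
    (chrom, start, end) locus to a depth multiplier emulating a collapsed
    tandem array of that many copies.
    """
    rows = []
    for _, c in annotation.chromosomes.iterrows():
        for start in range(0, int(c["length"]), window):
            rows.append(
                {
                    "chrom": c["chrom"],
                    "start": start,
                    "end": min(start + window, int(c["length"])),
                    "copies": 2,
                    "multiplier": 1.0,
                }
            )
    cmap = pd.DataFrame(rows)

    def windows_in(chrom, start, end):
        return (cmap["chrom"] == chrom) & (cmap["start"] < end) & (
            cmap["end"] > start
        )

    for ev in he_events:
        cmap.loc[windows_in(ev.chrom, ev.start, ev.end), "copies"] = 0
        proj = project_interval(annotation, hmap, ev.chrom, ev.start, ev.end)
        if proj is None:
            raise ValueError(
                f"HE event {ev} contains no homeolog pairs; cannot project"
            )
        pchrom, pstart, pend, _ = proj
        cmap.loc[windows_in(pchrom, pstart, pend), "copies"] = 4
    for (chrom, start, end), mult in (rdna_loci or {}).items():
        cmap.loc[windows_in(chrom, start, end), "multiplier"] = mult
    return cmap


def simulate_coverage(
    annotation: GenomeAnnotation,
    copy_map: pd.DataFrame,
    depth_mean: float,
    seed: int,
) -> tuple[CoverageTrack, GroundTruth]:
    """Poisson window depths: depth ~ Poisson(depth_mean x copies/2 x mult)."""
    if depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    rng = np.random.default_rng([int(seed), _STREAM["coverage"]])
    lam = (
        depth_mean
        * copy_map["copies"].to_numpy() / 2.0
        * copy_map["multiplier"].to_numpy()
    )
    windows = copy_map[["chrom", "start", "end"]].copy()
    windows["depth"] = rng.poisson(lam).astype(float)
    return CoverageTrack(windows), GroundTruth(copy_map=copy_map.copy())


# ---------------------------------------------------------------------------
# Hi-C contacts


def simulate_contacts(
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    he_events: tuple[HEEvent, ...] = (),
    background: float = 5.0,
    spike: float = 10.0,
    seed: int = 0,
    bin_width: int = 25_000,
    cis_scale: float = 50.0,
    flank: int = 1,
    noise: bool = True,
) -> ContactMatrix:
    """Symmetric binned contacts: distance-decay cis, uniform trans + spikes.

    Trans bin pairs within ``flank`` bins of each HE breakpoint pair have
    their expectation multiplied by ``spike``.  With ``noise=False`` the
    expectation matrix itself is returned.
    """
    if spike < 1:
        raise ValueError("spike must be >= 1")
    rng = np.random.default_rng([int(seed), _STREAM["contacts"]])
    bins = []
    for _, c in annotation.chromosomes.iterrows():
        for start in range(0, int(c["length"]), bin_width):
            bins.append({"chrom": c["chrom"], "start": start})
    bins = pd.DataFrame(bins)
    n = len(bins)
    chrom_arr = bins["chrom"].to_numpy()
    idx_in_chrom = bins.groupby("chrom").cumcount().to_numpy()

    same = chrom_arr[:, None] == chrom_arr[None, :]
    dist = np.abs(idx_in_chrom[:, None] - idx_in_chrom[None, :])
    expected = np.where(same, cis_scale / (1.0 + dist), background).astype(float)

    def bin_index(chrom, pos):
        sel = np.flatnonzero(
            (chrom_arr == chrom)
            & (bins["start"].to_numpy() <= pos)
            & (pos < bins["start"].to_numpy() + bin_width)
        )
        return int(sel[0]) if len(sel) else None

    for ev in he_events:
        proj = project_interval(annotation, hmap, ev.chrom, ev.start, ev.end)
        if proj is None:
            continue
        pchrom, pstart, pend, _ = proj
        for pos_a, pos_b in ((ev.start, pstart), (ev.end, pend)):
            ba = bin_index(ev.chrom, min(pos_a, _chrom_len(annotation, ev.chrom) - 1))
            bb = bin_index(pchrom, min(pos_b, _chrom_len(annotation, pchrom) - 1))
            if ba is None or bb is None:
                continue
            sel_a = np.flatnonzero(
                (chrom_arr == ev.chrom) & (np.abs(np.arange(n) - ba) <= flank)
            )
            sel_b = np.flatnonzero(
                (chrom_arr == pchrom) & (np.abs(np.arange(n) - bb) <= flank)
            )
            expected[np.ix_(sel_a, sel_b)] = background * spike
            expected[np.ix_(sel_b, sel_a)] = background * spike

    if noise:
        iu = np.triu_indices(n)
        draws = rng.poisson(expected[iu]).astype(float)
        mat = np.zeros((n, n))
        mat[iu] = draws
        mat = mat + mat.T - np.diag(np.diag(mat))
    else:
        mat = expected
    return ContactMatrix(bins, mat)


def _chrom_len(annotation: GenomeAnnotation, chrom: str) -> int:
    return int(
        annotation.chromosomes.set_index("chrom").loc[chrom, "length"]
    )


def simulate_discordant_pairs(
    annotation: GenomeAnnotation,
    hmap: HomeologMap,
    he_events: tuple[HEEvent, ...],
    n_pairs_per_breakpoint: int = 6,
    jitter: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Read pairs linking the two subgenomes at each HE breakpoint."""
    rng = np.random.default_rng([int(seed), _STREAM["pairs"]])
    rows = []
    for ev in he_events:
        proj = project_interval(annotation, hmap, ev.chrom, ev.start, ev.end)
        if proj is None:
            continue
        pchrom, pstart, pend, _ = proj
        for pos_a, pos_b in ((ev.start, pstart), (ev.end, pend)):
            for _ in range(n_pairs_per_breakpoint):
                rows.append(
                    {
                        "chrom_a": ev.chrom,
                        "pos_a": int(pos_a + rng.integers(-jitter, jitter + 1)),
                        "chrom_b": pchrom,
                        "pos_b": int(pos_b + rng.integers(-jitter, jitter + 1)),
                    }
                )
    return pd.DataFrame(rows, columns=["chrom_a", "pos_a", "chrom_b", "pos_b"])
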