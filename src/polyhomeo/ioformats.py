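"""Readers and writers for the pipeline's external formats.

Formats covered: GFF3 gene annotation with subgenome-labelled chromosomes
(``##subgenome`` directives), homeolog pair TSV, count matrix + sample
metadata TSV, bedGraph coverage, triplet contact TSV with a bin table,
rectangular TE presence/absence TSV, tabular alignment hits, and a VCF-lite
SNP table with effect classes.

Conventions: all interval coordinates are 0-based half-open in memory;
GFF3's 1-based inclusive coordinates are converted only at this boundary.
Writers format floats with 6 significant digits so that write -> read is the
identity.  Contact triplets are stored upper-triangle and mirrored on read.

The TE-call dialect is a rectangular TSV (chrom, pos, family, then one column
per accession holding 1/0/NA), i.e. the presence/absence abstraction that a
population TE caller such as PoPoolationTE2 ultimately produces.  A converter
from PoPoolationTE2's native signature output would map its (chromosome,
position, TE family, per-sample support) records onto these columns; only the
rectangular form is consumed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd

from .cnv_coverage import CoverageTrack
from .homeolog_expr import ExpressionMatrix
from .te_dynamics import TEInsertionMatrix

__all__ = [
    "FormatError",
    "IntegrityError",
    "GenomeAnnotation",
    "HomeologMap",
    "ContactMatrix",
    "read_annotation",
    "write_annotation",
    "read_pairs",
    "write_pairs",
    "read_counts",
    "write_counts",
    "read_coverage",
    "write_coverage",
    "read_contacts",
    "write_contacts",
    "read_te_calls",
    "write_te_calls",
    "read_hits",
    "write_hits",
    "read_snps",
    "write_snps",
]

SUBGENOMES = ("TH", "AR")
FLOAT_FMT = "%.6g"


class FormatError(ValueError):
    """A file violates its declared column/value contract."""


class IntegrityError(ValueError):
    """Cross-references within a file do not resolve."""


@dataclass
class GenomeAnnotation:
    """Chromosomes (with subgenome labels) and non-overlapping gene intervals.

    ``chromosomes`` columns: chrom, length, subgenome.  ``genes`` columns:
    gene_id, chrom, start, end, strand, subgenome, partner (internal 0-based
    half-open coordinates; partner may be None for unpaired genes).
    """

    chromosomes: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.chromosomes["subgenome"]) - set(SUBGENOMES)
        if bad:
            raise FormatError(f"unknown subgenome labels: {sorted(bad)}")
        if self.genes["gene_id"].duplicated().any():
            raise IntegrityError("duplicate gene ids")
        lengths = self.chromosomes.set_index("chrom")["length"]
        for _, g in self.genes.iterrows():
            if g["chrom"] not in lengths.index:
                raise IntegrityError(f"gene {g['gene_id']} on unknown chromosome")
            if not (0 <= g["start"] < g["end"] <= lengths[g["chrom"]]):
                raise IntegrityError(
                    f"gene {g['gene_id']} outside chromosome bounds"
                )
        self._check_partners()

    def _check_partners(self) -> None:
        by_id = self.genes.set_index("gene_id")["partner"]
        for gid, partner in by_id.items():
            if partner is None or (isinstance(partner, float) and np.isnan(partner)):
                continue
            if partner not in by_id.index:
                raise IntegrityError(f"dangling partner id {partner!r} of {gid}")
            back = by_id[partner]
            if back != gid:
                raise IntegrityError(
                    f"partner link {gid}->{partner} not reciprocated"
                )

    @property
    def chrom_subgenome(self) -> dict[str, str]:
        return dict(
            zip(self.chromosomes["chrom"], self.chromosomes["subgenome"])
        )

    def genes_on(self, subgenome: str) -> pd.DataFrame:
        return self.genes[self.genes["subgenome"] == subgenome]

    def genes_in(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Genes fully contained in the 0-based half-open interval."""
        g = self.genes
        return g[(g["chrom"] == chrom) & (g["start"] >= start) & (g["end"] <= end)]


@dataclass
class HomeologMap:
    """Bijective 1:1 pairing of genes between the two subgenomes."""

    pairs: pd.DataFrame  # pair_id, th_gene, ar_gene

    def __post_init__(self) -> None:
        for col in ("th_gene", "ar_gene"):
            if self.pairs[col].duplicated().any():
                raise IntegrityError(f"{col} repeated; pairing not bijective")

    @property
    def th_to_ar(self) -> dict[str, str]:
        return dict(zip(self.pairs["th_gene"], self.pairs["ar_gene"]))

    @property
    def ar_to_th(self) -> dict[str, str]:
        return dict(zip(self.pairs["ar_gene"], self.pairs["th_gene"]))

    def partner_of(self, gene: str) -> str | None:
        return self.th_to_ar.get(gene) or self.ar_to_th.get(gene)


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C contact counts (default 25 kb bins)."""

    bins: pd.DataFrame  # bin_id (index), chrom, start
    matrix: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.matrix.shape != (n, n):
            raise FormatError("contact matrix shape does not match bin table")
        if (self.matrix < 0).any():
            raise FormatError("negative contact counts")
        if not np.allclose(self.matrix, self.matrix.T):
            raise FormatError("contact matrix not symmetric")

    def chrom_bins(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())

    def bin_of(self, chrom: str, pos: int) -> int:
        sel = self.bins[(self.bins["chrom"] == chrom)]
        width = int(np.diff(sorted(sel["start"]))[0]) if len(sel) > 1 else int(
            sel["start"].max() + 1
        )
        hit = sel[(sel["start"] <= pos) & (pos < sel["start"] + width)]
        if hit.empty:
            raise KeyError(f"no bin covers {chrom}:{pos}")
        return int(hit.index[0])


# ---------------------------------------------------------------------------
# GFF3 annotation


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, c in annotation.chromosomes.iterrows():
            fh.write(f"##sequence-region {c['chrom']} 1 {int(c['length'])}\n")
        for _, c in annotation.chromosomes.iterrows():
            fh.write(f"##subgenome {c['chrom']} {c['subgenome']}\n")
        for _, g in annotation.genes.iterrows():
            attrs = f"ID={g['gene_id']}"
            if g["partner"] is not None and not (
                isinstance(g["partner"], float) and np.isnan(g["partner"])
            ):
                attrs += f";Partner={g['partner']}"
            fh.write(
                "\t".join(
                    [
                        str(g["chrom"]),
                        "polyhomeo",
                        "gene",
                        str(int(g["start"]) + 1),  # to 1-based inclusive
                        str(int(g["end"])),
                        ".",
                        str(g["strand"]),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_annotation(path: str | Path) -> GenomeAnnotation:
    """Read a GFF3 annotation; subgenomes come from ``##subgenome`` directives."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    chrom_len: dict[str, int] = {}
    chrom_sub: dict[str, str] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts[0] == "sequence-region" and len(parts) == 4:
            chrom_len[parts[1]] = int(parts[3])
        elif parts[0] == "subgenome" and len(parts) == 3:
            if parts[2] not in SUBGENOMES:
                raise FormatError(f"unknown subgenome label {parts[2]!r}")
            chrom_sub[parts[1]] = parts[2]
    missing = set(chrom_len) - set(chrom_sub)
    if missing:
        raise FormatError(f"chromosomes without subgenome label: {sorted(missing)}")
    chromosomes = pd.DataFrame(
        {
            "chrom": list(chrom_len),
            "length": [chrom_len[c] for c in chrom_len],
            "subgenome": [chrom_sub[c] for c in chrom_len],
        }
    )
    rows = []
    for feat in db.features_of_type("gene"):
        partner = feat.attributes.get("Partner", [None])[0]
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start - 1,  # to 0-based half-open
                "end": feat.end,
                "strand": feat.strand,
                "subgenome": chrom_sub.get(feat.seqid),
                "partner": partner,
            }
        )
    genes = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "subgenome",
                 "partner"],
    )
    return GenomeAnnotation(chromosomes, genes)


# ---------------------------------------------------------------------------
# homeolog pairs


def write_pairs(hmap: HomeologMap, path: str | Path) -> None:
    hmap.pairs.to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> HomeologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"pair_id", "th_gene", "ar_gene"}
    if not need.issubset(df.columns):
        raise FormatError(f"pair table needs columns {sorted(need)}")
    return HomeologMap(df)


# ---------------------------------------------------------------------------
# expression counts


def write_counts(matrix: ExpressionMatrix, counts_path: str | Path,
                 meta_path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "subgenome", matrix.gene_subgenome)
    out.insert(0, "length", matrix.lengths)
    out.index.name = "gene_id"
    out.to_csv(counts_path, sep="\t")
    meta = matrix.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(meta_path, sep="\t")


def read_counts(counts_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    for col in ("length", "subgenome"):
        if col not in df.columns:
            raise FormatError(f"counts table needs a {col!r} column")
    lengths = df.pop("length")
    subg = df.pop("subgenome")
    counts = df
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise FormatError("non-numeric counts")
    if (counts.to_numpy() < 0).any():
        raise FormatError("negative counts")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    if "replicate" not in meta.columns:
        raise FormatError("metadata needs a replicate column")
    return ExpressionMatrix(counts, lengths, meta, subg)


# ---------------------------------------------------------------------------
# coverage (bedGraph)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    track.windows.to_csv(
        path, sep="\t", header=False, index=False, float_format=FLOAT_FMT
    )


def read_coverage(path: str | Path) -> CoverageTrack:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None,
            names=["chrom", "start", "end", "depth"],
            dtype={"start": int, "end": int, "depth": float},
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"malformed bedGraph: {exc}") from exc
    if df.isna().any().any():
        raise FormatError("ragged or non-numeric bedGraph rows")
    return CoverageTrack(df)


# ---------------------------------------------------------------------------
# contacts (bin table + upper-triangle triplets)


def write_contacts(contacts: ContactMatrix, triplet_path: str | Path,
                   bins_path: str | Path) -> None:
    bins = contacts.bins.copy()
    bins.index.name = "bin_id"
    bins.to_csv(bins_path, sep="\t")
    iu = np.triu_indices(len(bins))
    vals = contacts.matrix[iu]
    nz = vals != 0
    trip = pd.DataFrame(
        {"bin_i": iu[0][nz], "bin_j": iu[1][nz], "count": vals[nz]}
    )
    trip.to_csv(triplet_path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_contacts(triplet_path: str | Path, bins_path: str | Path) -> ContactMatrix:
    bins = pd.read_csv(bins_path, sep="\t", index_col="bin_id")
    trip = pd.read_csv(triplet_path, sep="\t")
    if not {"bin_i", "bin_j", "count"}.issubset(trip.columns):
        raise FormatError("triplet table needs bin_i, bin_j, count")
    n = len(bins)
    mat = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for _, t in trip.iterrows():
        i, j, c = int(t["bin_i"]), int(t["bin_j"]), float(t["count"])
        if not (0 <= i < n and 0 <= j < n):
            raise FormatError(f"triplet bin id out of range: ({i}, {j})")
        key = (min(i, j), max(i, j))
        if key in seen and seen[key] != c:
            raise FormatError(f"asymmetric contact triplet at {key}")
        seen[key] = c
        mat[key[0], key[1]] = c
        mat[key[1], key[0]] = c
    return ContactMatrix(bins, mat)


# ---------------------------------------------------------------------------
# TE calls


def write_te_calls(matrix: TEInsertionMatrix, path: str | Path) -> None:
    out = matrix.sites[["chrom", "pos", "family"]].copy()
    calls = matrix.calls.copy()
    for col in calls.columns:
        out[col] = (
            calls[col]
            .map({1.0: "1", 0.0: "0"})
            .where(calls[col].notna(), "NA")
        )
    out.to_csv(path, sep="\t", index=False)


def read_te_calls(
    path: str | Path,
    subgenome_of: dict[str, str] | None = None,
    panel: str = "",
) -> TEInsertionMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = {"chrom", "pos", "family"}
    if not need.issubset(df.columns):
        raise FormatError(f"TE call table needs columns {sorted(need)}")
    acc_cols = [c for c in df.columns if c not in need]
    if not acc_cols:
        raise FormatError("TE call table declares no accession columns")
    sites = df[["chrom", "pos", "family"]].copy()
    sites["pos"] = sites["pos"].astype(int)
    if (sites["pos"] < 1).any():
        raise FormatError("TE positions must be >= 1")
    if sites.duplicated(["chrom", "pos", "family"]).any():
        raise FormatError("duplicate (chrom, pos, family) rows")
    sites["subgenome"] = [
        subgenome_of[c] if subgenome_of is not None else str(c)[:2].upper()
        for c in sites["chrom"]
    ]
    calls = pd.DataFrame(index=df.index, columns=acc_cols, dtype=float)
    for col in acc_cols:
        raw = df[col].astype(str)
        ok = raw.isin(["1", "0", "NA"])
        if not ok.all():
            bad = raw[~ok].iloc[0]
            raise FormatError(f"TE call cell outside {{1,0,NA}}: {bad!r}")
        calls[col] = raw.map({"1": 1.0, "0": 0.0, "NA": np.nan})
    return TEInsertionMatrix(sites.reset_index(drop=True),
                             calls.reset_index(drop=True), panel=panel)


# ---------------------------------------------------------------------------
# alignment hits


HIT_COLUMNS = ["query", "subject", "pident", "qcov_frac"]
HIT_OPTIONAL = ["qstart", "qend", "sstart", "send", "aln_len", "subject_genome",
                "qlen"]


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not set(HIT_COLUMNS).issubset(df.columns):
        raise FormatError(f"hit table needs columns {HIT_COLUMNS}")
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise FormatError("percent identity outside [0, 100]")
    if ((df["qcov_frac"] < 0) | (df["qcov_frac"] > 1)).any():
        raise FormatError("aligned query fraction outside [0, 1]")
    return df


# ---------------------------------------------------------------------------
# SNPs (VCF-lite TSV)


EFFECT_CLASSES = ("synonymous", "nonsynonymous", "other")


def write_snps(snps: pd.DataFrame, path: str | Path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_snps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "ref", "alt", "effect", "ancestral"}
    if not need.issubset(df.columns):
        raise FormatError(f"SNP table needs columns {sorted(need)}")
    df["effect"] = [
        e if e in EFFECT_CLASSES[:2] else "other" for e in df["effect"]
    ]
    acc_cols = [c for c in df.columns if c not in need]
    for col in acc_cols:
        raw = df[col].astype(str)
        ok = raw.isin(["1", "0", "NA", "nan"])
        if not ok.all():
            raise FormatError(f"genotype cell outside {{1,0,NA}} in {col!r}")
        df[col] = raw.map({"1": 1.0, "0": 0.0}).astype(float)
    return df


# ---------------------------------------------------------------------------
# ground truth (JSON)


def write_truth(truth: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=default)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
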