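"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* All genomic coordinates are 1-based inclusive internally (PLINK MAP /
  GFF3 convention).  BED inputs are shifted on read (start + 1) and on
  write (start - 1).
* Genotype dosage is the count of the B allele in {0, 1, 2}; missing
  calls are ``numpy.nan``, never 0.  For PED/MAP input, B is the minor
  allele at load time (lexicographic tie-break); for VCF input, B is ALT.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PipelineError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(PipelineError):
    """Input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

#: Background genome length used for enrichment (bp): the configured
#: genome's total length; the porcine default is 2.7 Gb.
PORCINE_GENOME_BP = 2_700_000_000


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosome names and lengths in bp."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom name/length count mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("duplicate chromosome names")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValidationError("chromosome lengths must be > 0")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_names

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom_names, "length": self.chrom_lengths}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeBuild":
        return cls(tuple(df["chrom"].astype(str)), tuple(int(x) for x in df["length"]))


@dataclass
class GenotypeMatrix:
    """samples x variants allele-dosage matrix; missing is NaN."""

    dosages: np.ndarray  # float array, values in {0,1,2,nan}
    sample_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValidationError("dosage matrix shape does not match id lists")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValidationError("dosages must lie in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.variant_ids.index(variant_id)]

    def subset_variants(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in keep]
        return GenotypeMatrix(self.dosages[:, idx], list(self.sample_ids), list(keep))


VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "allele_a", "allele_b"]
TRAIT_QTL_COLUMNS = ["trait", "category", "breed", "chrom", "start", "end"]

#: The five trait categories of the reference QTL database.
QTL_CATEGORIES = (
    "Meat and carcass",
    "Health",
    "Production",
    "Exterior",
    "Reproduction",
)


def make_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a variant table (one row per variant)."""
    missing = [c for c in ("variant_id", "chrom", "pos") if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing columns {missing}")
    df = df.copy()
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValidationError(f"duplicate variant id {dup!r}")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValidationError("variant positions must be >= 1")
    for col in ("allele_a", "allele_b"):
        if col not in df.columns:
            df[col] = "A" if col == "allele_a" else "B"
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df[VARIANT_COLUMNS]


def make_gene_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene id in annotation")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        raise ValidationError("gene start > end")
    if "strand" not in df.columns:
        df["strand"] = "."
    return df[["gene_id", "chrom", "start", "end", "strand"]].reset_index(drop=True)


def make_sample_table(df: pd.DataFrame, covariates: Sequence[str] | None = None) -> pd.DataFrame:
    """Validate a per-sample metadata table (group, EBV, covariates)."""
    for col in ("sample_id", "group", "ebv"):
        if col not in df.columns:
            raise ValidationError(f"sample table missing column {col!r}")
    df = df.copy().reset_index(drop=True)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample id")
    levels = set(df["group"])
    if levels - {"low", "medium", "high"}:
        raise ValidationError(f"unknown group labels {levels - {'low','medium','high'}}")
    cov = list(covariates) if covariates is not None else [
        c for c in df.columns if c not in ("sample_id", "group", "ebv")
    ]
    if df[cov + ["ebv"]].isna().any().any():
        raise ValidationError("missing EBV or covariate values in sample table")
    return df


# ---------------------------------------------------------------------------
# PED/MAP and VCF genotypes
# ---------------------------------------------------------------------------

_PED_MISSING = "0"


def read_genotypes(path: str | Path, map_path: str | Path | None = None):
    """Read genotypes from a PED/MAP pair or an uncompressed VCF.

    Returns ``(GenotypeMatrix, variant_table)``.  Dosage is the count of
    the B allele (minor at load for PED; ALT for VCF).  Only biallelic
    records are accepted.
    """
    path = Path(path)
    if path.suffix == ".vcf":
        return _read_vcf(path)
    if path.suffix == ".ped":
        if map_path is None:
            map_path = path.with_suffix(".map")
        return _read_ped_map(path, Path(map_path))
    raise ValidationError(f"unrecognised genotype format: {path.name}")


def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError("MAP line needs chrom, id, cM, pos", lineno)
            rows.append((parts[1], parts[0], int(parts[3])))
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])
    if df["variant_id"].duplicated().any():
        raise ValidationError("duplicate variant id in MAP file")
    return df


def _read_ped_map(ped_path: Path, map_path: Path):
    vmap = _read_map(map_path)
    n_var = len(vmap)
    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise ParseError(
                    f"PED row has {len(parts)} fields, expected {6 + 2 * n_var}",
                    lineno,
                )
            sample_ids.append(parts[1])
            allele_rows.append(parts[6:])
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample id in PED file")

    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), n_var, 2)
    dosages = np.full((len(sample_ids), n_var), np.nan)
    allele_a, allele_b = [], []
    for j in range(n_var):
        col = alleles[:, j, :]
        observed = col[col != _PED_MISSING]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise ValidationError(
                f"variant {vmap['variant_id'][j]!r} has >2 alleles: {uniq}"
            )
        if not uniq:
            allele_a.append("A")
            allele_b.append("B")
            continue
        if len(uniq) == 1:
            a, b = uniq[0], uniq[0]
        else:
            # B = minor allele at load time; lexicographic tie-break.
            counts = {u: int((observed == u).sum()) for u in uniq}
            b = min(uniq, key=lambda u: (counts[u], -ord(u[0])))
            a = [u for u in uniq if u != b][0]
            if counts[a] == counts[b]:
                a, b = sorted(uniq)
        allele_a.append(a)
        allele_b.append(b)
        called = (col != _PED_MISSING).all(axis=1)
        dosages[called, j] = (col[called] == b).sum(axis=1)

    vmap["allele_a"] = allele_a
    vmap["allele_b"] = allele_b
    variants = make_variant_table(vmap)
    # reorder dosage columns to the canonical (chrom, pos) sort
    order = [list(vmap["variant_id"]).index(v) for v in variants["variant_id"]]
    matrix = GenotypeMatrix(
        dosages[:, order], sample_ids, list(variants["variant_id"])
    )
    return matrix, variants


def _read_vcf(path: Path):
    import pysam

    sample_ids: list[str] = []
    rows, dosage_cols = [], []
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValidationError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos} "
                    f"(ALT {','.join(alts) or '.'})"
                )
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            rows.append((vid, rec.chrom, rec.pos, rec.ref, alts[0]))
            col = np.full(len(sample_ids), np.nan)
            for i, s in enumerate(sample_ids):
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                col[i] = sum(gt)
            dosage_cols.append(col)
    variants = make_variant_table(
        pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    )
    raw_ids = [r[0] for r in rows]
    order = [raw_ids.index(v) for v in variants["variant_id"]]
    dosages = np.column_stack(dosage_cols)[:, order] if dosage_cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(dosages, sample_ids, list(variants["variant_id"])), variants


def write_genotypes(matrix: GenotypeMatrix, variants: pd.DataFrame,
                    ped_path: str | Path, map_path: str | Path | None = None) -> None:
    """Write a PED/MAP pair (dosage = count of allele_b)."""
    ped_path = Path(ped_path)
    if map_path is None:
        map_path = ped_path.with_suffix(".map")
    v = variants.set_index("variant_id").loc[matrix.variant_ids]
    with open(map_path, "w") as fh:
        for vid, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{vid}\t0\t{row['pos']}\n")
    a = v["allele_a"].to_numpy()
    b = v["allele_b"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(matrix.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j in range(matrix.n_variants):
                d = matrix.dosages[i, j]
                if np.isnan(d):
                    fields += [_PED_MISSING, _PED_MISSING]
                else:
                    nb = int(d)
                    fields += [b[j]] * nb + [a[j]] * (2 - nb)
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Count matrices, sample tables, gene annotation, trait-QTL tables
# ---------------------------------------------------------------------------


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples integer count matrix from TSV."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, engine="python")
    except pd.errors.ParserError as exc:
        raise ParseError(f"ragged or malformed count matrix: {exc}") from exc
    if df.isna().any().any():
        raise ValidationError("count matrix has missing cells (ragged rows?)")
    if df.index.duplicated().any():
        raise ValidationError(f"duplicated gene id {df.index[df.index.duplicated()][0]!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError("non-numeric cell in count matrix")
    if (values < 0).any():
        raise ValidationError("negative count")
    if not np.equal(np.mod(values, 1), 0).all():
        raise ValidationError("non-integer count")
    df = df.astype(int)
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    return make_sample_table(pd.read_csv(path, sep="\t"))


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene annotation from GFF3 (1-based) or BED (0-based start)."""
    path = Path(path)
    if path.suffix in (".gff", ".gff3"):
        return _read_gff3(path)
    if path.suffix == ".bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            usecols=range(6),
        )
        df["start"] = df["start"].astype(int) + 1  # BED half-open -> 1-based
        df["chrom"] = df["chrom"].astype(str)
        return make_gene_annotation(df)
    raise ValidationError(f"unrecognised gene annotation format: {path.name}")


def _read_gff3(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ParseError("GFF3 line must have 9 fields", lineno)
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ParseError("gene feature without ID attribute", lineno)
            rows.append((gid.removeprefix("gene:"), str(parts[0]),
                         int(parts[3]), int(parts[4]), parts[6]))
    return make_gene_annotation(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    )


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["start"] = out["start"] - 1  # back to BED half-open
    out["score"] = 0
    out[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_trait_qtl(path: str | Path, genome: GenomeBuild | None = None) -> pd.DataFrame:
    """Read the trait-QTL interval table (1-based inclusive coordinates)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAIT_QTL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"trait-QTL table missing columns {missing}")
    return make_trait_qtl_table(df, genome)


def make_trait_qtl_table(df: pd.DataFrame, genome: GenomeBuild | None = None) -> pd.DataFrame:
    df = df.copy().reset_index(drop=True)
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise ValidationError(f"trait-QTL row {bad[0]}: start > end")
    if genome is not None:
        for i, row in df.iterrows():
            if row["chrom"] not in genome:
                raise ValidationError(f"trait-QTL row {i}: unknown chromosome {row['chrom']!r}")
            if row["end"] > genome.length_of(row["chrom"]) or row["start"] < 1:
                raise ValidationError(f"trait-QTL row {i}: interval outside chromosome")
    return df[TRAIT_QTL_COLUMNS]


def write_trait_qtl(df: pd.DataFrame, path: str | Path) -> None:
    df[TRAIT_QTL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic tab-delimited output with a header row."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

#: The four taint-relevant trait names used for candidate selection.
BOAR_TAINT_TRAITS = (
    "Fat androstenone level",
    "indole, laboratory",
    "Off-Flavor Score",
    "Overall impression, sensory panel",
)


@dataclass
class RunConfig:
    """All stage thresholds with their published defaults, plus run state."""

    call_rate_min: float = 0.95          # keep variants with call rate > this
    maf_min: float = 0.05                # keep variants with MAF > this
    hwe_p_min: float = 1e-4              # keep variants with exact-test p > this
    ld_window_bp: int = 5_000
    ld_step_bp: int = 5_000
    ld_r2_max: float = 0.8
    mean_count_min: float = 5.0          # keep genes with mean count > this
    cis_window_bp: int = 1_000_000
    p_cis: float = 1e-3
    p_trans: float = 1e-6
    fdr_target: float = 0.05
    network_threshold: float = 0.5
    breed_min_qtls: int = 1_000
    genome_background_bp: int = PORCINE_GENOME_BP
    candidate_ebv_max: float = -0.0699208
    boar_taint_traits: tuple[str, ...] = BOAR_TAINT_TRAITS
    use_scan_weights: bool = False
    merge_trait_intervals: bool = True
    density_scale: float = 1e8
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["boar_taint_traits"] = list(self.boar_taint_traits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "boar_taint_traits" in d:
            d["boar_taint_traits"] = tuple(d["boar_taint_traits"])
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
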