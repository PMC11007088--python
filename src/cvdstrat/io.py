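"""In-memory containers and plain-text readers/writers.

Genotypes travel either as a TSV dosage matrix plus a variant-metadata
TSV, or as a minimal VCF with a ``DS`` (dosage) FORMAT field.  Weight
panels are per-trait TSVs keyed by variant id and effect allele; the
cohort is a flat CSV, one row per participant.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "WeightPanel",
    "COHORT_COLUMNS",
    "VARIANT_META_COLUMNS",
    "read_dosage_tsv",
    "read_weight_panel",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_vcf",
    "read_vcf_dosages",
]

#: Required columns of the per-variant metadata table.
VARIANT_META_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "maf", "call_rate", "hwe_p", "info_quality",
]

#: Canonical cohort schema; ``sex`` is 1 for male, 0 for female.
COHORT_COLUMNS = [
    "sample_id", "sex", "age", "tc", "hdl", "sbp",
    "bp_treated", "smoker", "diabetes", "prevalent_cvd", "time_years", "event",
]


@dataclass
class GenotypeMatrix:
    """Per-sample, per-variant effect-allele dosages in [0, 2].

    Missing dosages are ``NaN`` (the sentinel outside [0, 2] from which
    call rates are computed).  ``variants`` carries one metadata row per
    column of ``dosages``.
    """

    dosages: np.ndarray  # (n_samples, n_variants), float, NaN = missing
    sample_ids: list[str]
    variants: pd.DataFrame

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in ("variant_id", "effect_allele") if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant metadata lacks column(s): {missing}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self) -> pd.Series:
        """Map variant_id -> column position."""
        return pd.Series(np.arange(self.n_variants), index=self.variants["variant_id"].to_numpy())

    def take_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def take_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            dosages=self.dosages[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants.copy(),
        )

    # -- plain-text round trip -------------------------------------------------

    def write_tsv(self, dosage_path, meta_path) -> None:
        df = pd.DataFrame(self.dosages, index=pd.Index(self.sample_ids, name="sample_id"),
                          columns=self.variants["variant_id"].to_numpy())
        df.to_csv(dosage_path, sep="\t", float_format="%.6g", na_rep="NA")
        self.variants.to_csv(meta_path, sep="\t", index=False, float_format="%.6g")


@dataclass
class WeightPanel:
    """Per-variant scoring weights for one trait."""

    trait: str
    table: pd.DataFrame  # columns: variant_id, effect_allele, weight

    def __post_init__(self):
        need = {"variant_id", "effect_allele", "weight"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"weight panel for {self.trait} lacks {need - set(self.table.columns)}")

    def __len__(self) -> int:
        return len(self.table)

    def write_tsv(self, path) -> None:
        self.table[["variant_id", "effect_allele", "weight"]].to_csv(
            path, sep="\t", index=False, float_format="%.10g")


def read_dosage_tsv(dosage_path, meta_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values="NA")
    meta = pd.read_csv(meta_path, sep="\t")
    meta_ids = meta["variant_id"].astype(str).to_numpy()
    if list(df.columns) != list(meta_ids):
        meta = meta.set_index("variant_id").loc[df.columns].reset_index()
    return GenotypeMatrix(df.to_numpy(float), [str(s) for s in df.index], meta)


def read_weight_panel(path, trait: str) -> WeightPanel:
    return WeightPanel(trait, pd.read_csv(path, sep="\t"))


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks column(s): {missing}")
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# VCF with dosage FORMAT field

def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 file whose per-sample FORMAT field carries the
    effect-allele dosage (``DS``); ALT is the effect allele."""
    v = geno.variants
    chrom = v["chrom"] if "chrom" in v else pd.Series(["1"] * len(v))
    pos = v["pos"] if "pos" in v else pd.Series(np.arange(1, len(v) + 1))
    other = v["other_allele"] if "other_allele" in v else pd.Series(["A"] * len(v))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        fh.write("##INFO=<ID=INFO,Number=1,Type=Float,Description=\"Imputation quality\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        info_q = v["info_quality"] if "info_quality" in v else pd.Series([1.0] * len(v))
        for j in range(geno.n_variants):
            ds = geno.dosages[:, j]
            cells = "\t".join("." if np.isnan(d) else f"{d:.4g}" for d in ds)
            fh.write(f"{chrom.iloc[j]}\t{pos.iloc[j]}\t{v['variant_id'].iloc[j]}\t"
                     f"{other.iloc[j]}\t{v['effect_allele'].iloc[j]}\t.\tPASS\t"
                     f"INFO={info_q.iloc[j]:.4g}\tDS\t{cells}\n")


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Read back a DS-format VCF written by :func:`write_vcf` (plain text)."""
    header = None
    rows, meta = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.rstrip("\n").split("\t")
                continue
            f = line.rstrip("\n").split("\t")
            meta.append({"variant_id": f[2], "chrom": f[0], "pos": int(f[1]),
                         "effect_allele": f[4], "other_allele": f[3]})
            rows.append([np.nan if c == "." else float(c) for c in f[9:]])
    if header is None:
        raise ValueError(f"{path}: no #CHROM header line")
    samples = header[9:]
    dosages = np.array(rows, dtype=float).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, pd.DataFrame(meta))
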