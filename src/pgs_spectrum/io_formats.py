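"""Readers, writers and containers for the standard formats the pipeline touches.

Three tabular surfaces flow through the analysis:

* GWAS summary statistics — one row per variant with effect allele, log-odds
  (or linear) effect, standard error, two-sided p-value and GWAS sample size.
* Genotypes — a subjects x variants dosage matrix plus a variant table with
  chromosome, position and allele metadata (VCF or a plain TSV dialect).
* The cohort table — one row per subject with phenotypes and covariates.

Coordinates are 1-based inclusive (VCF convention) everywhere.  Odds-ratio
effect columns in external summary statistics are log-transformed to beta on
read.  Validation never silently drops data: every exclusion is logged with a
count, and hard failures name the offending variant ids or line numbers.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column order for summary-statistic files
SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N"]

#: alias map resolving common header synonyms to canonical names
SUMSTATS_ALIASES = {
    "SNP": "SNP", "ID": "SNP", "RSID": "SNP", "MARKERNAME": "SNP", "VARIANT_ID": "SNP",
    "CHR": "CHR", "CHROM": "CHR", "CHROMOSOME": "CHR",
    "BP": "BP", "POS": "BP", "POSITION": "BP", "BASE_PAIR_LOCATION": "BP",
    "A1": "A1", "EFFECT_ALLELE": "A1", "ALLELE1": "A1",
    "A2": "A2", "OTHER_ALLELE": "A2", "ALLELE2": "A2", "ALLELE0": "A2",
    "BETA": "BETA", "B": "BETA", "EFFECT": "BETA", "LOG_ODDS": "BETA",
    "OR": "OR", "ODDS_RATIO": "OR",
    "SE": "SE", "STDERR": "SE", "STANDARD_ERROR": "SE",
    "P": "P", "PVAL": "P", "PVALUE": "P", "P_VALUE": "P",
    "N": "N", "NTOT": "N", "SAMPLE_SIZE": "N",
}

MANDATORY = ["SNP", "A1", "A2", "BETA", "SE", "P"]


class FormatError(ValueError):
    """A file is structurally unreadable (missing mandatory columns etc.)."""


class ValidationError(ValueError):
    """A file parsed but contains invalid values; the message names offenders."""


class ConfigurationError(ValueError):
    """Invalid user-supplied parameter values."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SummaryStats:
    """A GWAS summary-statistic table for one source trait.

    ``table`` holds the canonical columns ``SNP CHR BP A1 A2 BETA SE P N``
    (CHR/BP/N may be absent for minimal inputs).  ``h2_zscore`` is the
    LD-score-regression heritability z-score used by :func:`select_gwas`.
    """

    name: str
    table: pd.DataFrame
    h2_zscore: float | None = None

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:  # round-trip identity in tests
        if not isinstance(other, SummaryStats):
            return NotImplemented
        if self.name != other.name:
            return False
        if (self.h2_zscore is None) != (other.h2_zscore is None):
            return False
        if self.h2_zscore is not None and not np.isclose(self.h2_zscore, other.h2_zscore):
            return False
        a, b = self.table.reset_index(drop=True), other.table.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind in "fc":
                if not np.allclose(a[c].to_numpy(float), b[c].to_numpy(float), equal_nan=True):
                    return False
            elif not (a[c].astype(str) == b[c].astype(str)).all():
                return False
        return True


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with subject metadata.

    ``dosages`` counts copies of the effect allele (``a1`` in the variant
    table; ALT by VCF convention), in {0,1,2} for hard calls or [0,2] for
    imputed dosages.  Missing genotypes are NaN and are mean-imputed per
    variant within ancestry group at scoring time, never at read time.
    """

    dosages: np.ndarray              # (n_subjects, n_variants) float
    subject_ids: np.ndarray          # (n_subjects,) str
    ancestry: np.ndarray             # (n_subjects,) str labels

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def group_mask(self, label: str) -> np.ndarray:
        return np.asarray(self.ancestry) == label

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[mask], self.subject_ids[mask],
                              self.ancestry[mask])


# VariantTable is a plain DataFrame with columns:
#   id, chrom, pos, a1 (effect allele), a2, and per-ancestry frequency
#   columns named freq_<label>.  Helper below validates the contract.
VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]


def validate_variant_table(variants: pd.DataFrame) -> None:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise FormatError(f"variant table missing columns: {missing}")
    if variants["id"].duplicated().any():
        dups = variants.loc[variants["id"].duplicated(), "id"].tolist()[:5]
        raise ValidationError(f"duplicate variant ids: {dups}")
    if (variants["a1"] == variants["a2"]).any():
        bad = variants.loc[variants["a1"] == variants["a2"], "id"].tolist()[:5]
        raise ValidationError(f"a1 == a2 for variants: {bad}")
    for _, sub in variants.groupby("chrom", sort=False):
        if not sub["pos"].is_monotonic_increasing:
            raise ValidationError("positions must be nondecreasing within chromosome")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, name: str | None = None,
                  h2_zscore: float | None = None) -> SummaryStats:
    """Read a tab-delimited (optionally gzipped) summary-statistic table.

    Header synonyms are resolved through :data:`SUMSTATS_ALIASES`; an ``OR``
    column is log-transformed to ``BETA``.  Raises :class:`FormatError` for
    missing mandatory columns and :class:`ValidationError` (naming variant
    ids / line numbers) for out-of-range values.
    """
    path = str(path)
    df = pd.read_csv(path, sep="\t", compression="infer", dtype={0: str})
    rename = {}
    for col in df.columns:
        key = col.strip().upper()
        if key in SUMSTATS_ALIASES:
            rename[col] = SUMSTATS_ALIASES[key]
    df = df.rename(columns=rename)
    if "BETA" not in df.columns and "OR" in df.columns:
        if (pd.to_numeric(df["OR"], errors="coerce") <= 0).any():
            bad = df.index[pd.to_numeric(df["OR"], errors="coerce") <= 0] + 2
            raise ValidationError(f"non-positive OR at lines {list(bad[:5])}")
        df["BETA"] = np.log(df["OR"].astype(float))
        df = df.drop(columns=["OR"])
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}; "
                          f"found {list(df.columns)}")

    df["SNP"] = df["SNP"].astype(str)
    for col in ("BETA", "SE", "P"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            lines = (df.index[vals.isna()] + 2).tolist()
            raise FormatError(f"{path}: malformed {col} at lines {lines[:10]}")
        df[col] = vals

    problems = []
    bad_p = (df["P"] <= 0) | (df["P"] > 1)
    if bad_p.any():
        problems.append(f"p outside (0,1] for ids {df.loc[bad_p, 'SNP'].tolist()[:10]}")
    bad_se = df["SE"] <= 0
    if bad_se.any():
        problems.append(f"se <= 0 for ids {df.loc[bad_se, 'SNP'].tolist()[:10]}")
    for col in ("A1", "A2"):
        df[col] = df[col].astype(str).str.upper()
        bad = ~df[col].isin(VALID_BASES)
        if bad.any():
            problems.append(f"invalid {col} base for ids {df.loc[bad, 'SNP'].tolist()[:10]}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    keep = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    keep += [c for c in df.columns if c not in keep]
    if name is None:
        name = path.rsplit("/", 1)[-1].split(".")[0]
    return SummaryStats(name=name, table=df[keep].reset_index(drop=True),
                        h2_zscore=h2_zscore)


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write tab-delimited summary statistics; gzip if the path ends in .gz."""
    path = str(path)
    cols = [c for c in SUMSTATS_COLUMNS if c in stats.table.columns]
    cols += [c for c in stats.table.columns if c not in cols]
    stats.table[cols].to_csv(path, sep="\t", index=False,
                             compression="gzip" if path.endswith(".gz") else None)


def select_gwas(traits: list[SummaryStats], z_min: float = 5.0) -> list[SummaryStats]:
    """Keep traits with LD-score heritability z-score strictly above ``z_min``.

    The comparison is strict (a boundary z-score equal to ``z_min`` is
    excluded).  Traits with missing metadata or incomplete mandatory columns
    are excluded and logged; input order is preserved.
    """
    kept = []
    for t in traits:
        if t.h2_zscore is None:
            logger.info("select_gwas: excluding %s (no h2 z-score metadata)", t.name)
            continue
        if not t.h2_zscore > z_min:
            logger.info("select_gwas: excluding %s (h2 z=%.3g <= %.3g)",
                        t.name, t.h2_zscore, z_min)
            continue
        if any(c not in t.table.columns for c in MANDATORY):
            logger.info("select_gwas: excluding %s (incomplete columns)", t.name)
            continue
        kept.append(t)
    logger.info("select_gwas: kept %d of %d traits", len(kept), len(traits))
    return kept


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

COHORT_BINARY = ["ps", "adhd", "adhd_symptoms", "depression", "mania",
                 "anxiety", "trauma"]
COHORT_SUBSTANCE = ["alcohol", "tobacco", "marijuana", "cocaine", "otc"]


def read_cohort(path) -> pd.DataFrame:
    """Read the per-subject phenotype/covariate TSV."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise FormatError(f"{path}: cohort table needs an 'id' column")
    if df["id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate subject ids")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF + TSV genotype dialects
# ---------------------------------------------------------------------------

def write_vcf(variants: pd.DataFrame, genotypes: GenotypeMatrix, path,
              fields: tuple[str, ...] = ("GT", "DS")) -> None:
    """Write a minimal VCF 4.2 with GT and/or DS FORMAT fields.

    REF is the other allele (a2), ALT the effect allele (a1), so that ALT
    dosage equals the stored effect-allele dosage.  Missing dosages are
    emitted as ``./.`` / ``.``.
    """
    validate_variant_table(variants)
    D = genotypes.dosages
    hard = np.all(np.isnan(D) | (D == np.round(D)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, genotypes.subject_ids)) + "\n")
        fmt = ":".join(fields)
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(variants.itertuples(index=False)):
            cells = []
            for d in D[:, j]:
                parts = []
                if "GT" in fields:
                    if np.isnan(d):
                        parts.append("./.")
                    elif hard:
                        parts.append(gt_map[int(round(d))])
                    else:
                        parts.append(gt_map[int(round(min(max(d, 0), 2)))])
                if "DS" in fields:
                    parts.append("." if np.isnan(d) else f"{d:g}")
                cells.append(":".join(parts))
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}"
                     f"\t.\t.\t.\t{fmt}\t" + "\t".join(cells) + "\n")


def read_genotypes_vcf(path, ancestry: dict | pd.Series | None = None
                       ) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read genotypes from a VCF with GT or DS fields.

    Dosage is the count of the ALT (effect) allele; DS takes precedence over
    GT when both are present.  Multi-allelic sites are skipped with a logged
    count.  ``ancestry`` optionally maps subject id -> ancestry label.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    rows, cols = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
            d[d < 0] = np.nan
        else:
            d = np.empty(len(samples))
            for i, g in enumerate(var.genotypes):
                alleles = g[:-1]
                d[i] = np.nan if -1 in alleles else float(sum(alleles))
        rows.append(dict(id=var.ID or f"{var.CHROM}:{var.POS}", chrom=str(var.CHROM),
                         pos=int(var.POS), a1=var.ALT[0], a2=var.REF))
        cols.append(d)
    if n_multi:
        logger.warning("read_genotypes_vcf: skipped %d multi-allelic site(s)", n_multi)
    variants = pd.DataFrame(rows)
    D = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    if ancestry is None:
        anc = np.asarray(["ALL"] * len(samples))
    else:
        anc = np.asarray([ancestry[s] for s in samples])
    return variants, GenotypeMatrix(D, samples, anc)


def write_genotypes_tsv(variants: pd.DataFrame, genotypes: GenotypeMatrix, path) -> None:
    """Documented TSV matrix dialect: one row per subject.

    Columns: ``subject_id``, ``ancestry``, then one column per variant id
    holding the effect-allele dosage (empty cell = missing).
    """
    df = pd.DataFrame(genotypes.dosages, columns=variants["id"])
    df.insert(0, "ancestry", genotypes.ancestry)
    df.insert(0, "subject_id", genotypes.subject_ids)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path, variants: pd.DataFrame) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    missing = [v for v in variants["id"] if v not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing variant columns {missing[:5]}")
    D = df[list(variants["id"])].to_numpy(float)
    return GenotypeMatrix(D, df["subject_id"].astype(str).to_numpy(),
                          df["ancestry"].astype(str).to_numpy())
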