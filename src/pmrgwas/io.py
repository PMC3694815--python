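"""PLINK transposed-text genotype I/O and mean imputation.

Genotypes are read from TPED files (one row per marker: chromosome,
marker id, genetic position in cM, bp position, then two alleles per
individual) with the matching TFAM sample file (family id, individual
id, father, mother, sex, phenotype).  Alleles are recoded to
minor-allele dosages in {0, 1, 2}, the minor allele being the one with
in-sample frequency <= 0.5 (alphabetically later allele on an exact
tie, so recoding is deterministic).

Missing genotype calls ("0 0", and half-calls like "A 0") become masked
entries; :func:`impute_missing_mean` replaces them with the per-marker
mean of the observed dosages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["chrom", "id", "cm", "bp"]
SAMPLE_COLUMNS = ["fid", "iid", "sex"]


class MalformedFileError(ValueError):
    """A TPED/TFAM file does not parse into a consistent dataset."""


@dataclass
class GenotypeDataset:
    """n x p minor-allele dosage matrix with per-marker metadata.

    ``dosages`` holds float values; pre-imputation entries under
    ``missing_mask`` are NaN, all others are in {0, 1, 2} (fractional
    values appear only after mean imputation).
    """

    dosages: np.ndarray                # (n, p) float
    markers: pd.DataFrame              # chrom, id, cm, bp
    samples: pd.DataFrame              # fid, iid, sex
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2 or min(self.dosages.shape) < 1:
            raise ValueError("dosages must be a non-empty n x p matrix")
        if len(self.markers) != self.p:
            raise ValueError("marker table length does not match p")
        if len(self.samples) != self.n:
            raise ValueError("sample table length does not match n")
        if self.markers["id"].duplicated().any():
            dup = self.markers["id"][self.markers["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.dosages)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask is not None and self.missing_mask.any())

    def marker_index(self, ids) -> np.ndarray:
        """Column indices for a sequence of marker ids."""
        lookup = pd.Index(self.markers["id"])
        idx = lookup.get_indexer(list(ids))
        if (idx < 0).any():
            missing = [m for m, i in zip(ids, idx) if i < 0]
            raise KeyError(f"marker ids not in dataset: {missing[:5]}")
        return idx

    def subset_markers(self, cols) -> "GenotypeDataset":
        cols = np.asarray(cols)
        return GenotypeDataset(
            self.dosages[:, cols],
            self.markers.iloc[cols].reset_index(drop=True),
            self.samples,
            None if self.missing_mask is None else self.missing_mask[:, cols],
        )


@dataclass
class PhenotypeVector:
    """Length-n phenotype; ``family`` is 'logistic' (0/1) or 'linear'."""

    values: np.ndarray
    family: str = "logistic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.family not in ("linear", "logistic"):
            raise ValueError("family must be 'linear' or 'logistic'")
        if self.family == "logistic" and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("logistic phenotype values must be 0/1")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CovariateMatrix:
    """n x c unpenalized design; first column is the all-ones intercept."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if len(self.labels) != self.values.shape[1]:
            raise ValueError("labels must match covariate columns")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")
        rank = np.linalg.matrix_rank(self.values)
        if rank < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    @classmethod
    def intercept_only(cls, n: int) -> "CovariateMatrix":
        return cls(np.ones((n, 1)), ["intercept"])

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def c(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# TPED / TFAM

def read_tped_tfam(tped_path, tfam_path, phenotype_family: str = "auto"
                   ) -> tuple[GenotypeDataset, PhenotypeVector]:
    """Read a TPED/TFAM pair into a dosage dataset and phenotype.

    Case/control phenotypes coded 2/1 are recoded to 1/0; phenotype
    values of -9 or 0 are treated as missing and those individuals are
    dropped with a warning.  With ``phenotype_family="auto"`` the
    phenotype is taken as case/control when all non-missing values are
    in {1, 2}, quantitative otherwise (missing then means -9 only).
    """
    tfam = pd.read_csv(tfam_path, sep=r"\s+", header=None,
                       names=["fid", "iid", "father", "mother", "sex", "pheno"],
                       dtype={"fid": str, "iid": str})
    n_all = len(tfam)
    if n_all == 0:
        raise MalformedFileError(f"{tfam_path}: no individuals")

    pheno_raw = tfam["pheno"].to_numpy(dtype=float)
    if phenotype_family == "auto":
        nonmiss = pheno_raw[(pheno_raw != -9)]
        family = "logistic" if np.all(np.isin(nonmiss, (0.0, 1.0, 2.0))) else "linear"
    else:
        family = phenotype_family
    if family == "logistic":
        missing_ind = np.isin(pheno_raw, (-9.0, 0.0))
        pheno = np.where(pheno_raw == 2.0, 1.0, 0.0)
    else:
        missing_ind = pheno_raw == -9.0
        pheno = pheno_raw.copy()
    keep = ~missing_ind
    if missing_ind.any():
        warnings.warn(f"dropping {int(missing_ind.sum())} individuals with "
                      "missing phenotype", stacklevel=2)

    marker_rows, dosage_cols, mask_cols = [], [], []
    with open(tped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4 + 2 * n_all:
                raise MalformedFileError(
                    f"{tped_path}:{lineno}: expected {4 + 2 * n_all} fields "
                    f"(2 alleles x {n_all} individuals), got {len(fields)}")
            chrom, mid, cm, bp = fields[:4]
            a1 = np.array(fields[4::2])
            a2 = np.array(fields[5::2])
            miss = (a1 == "0") | (a2 == "0")
            alleles = sorted(set(a1[~miss]) | set(a2[~miss]))
            if len(alleles) > 2:
                raise MalformedFileError(
                    f"marker {mid!r} is not biallelic: alleles {alleles}")
            dos = np.full(n_all, np.nan)
            if alleles:
                # minor = lower-frequency allele; alphabetically later on tie
                counts = {a: int((a1[~miss] == a).sum() + (a2[~miss] == a).sum())
                          for a in alleles}
                if len(alleles) == 1:
                    minor = alleles[0]
                    dos[~miss] = 0.0  # monomorphic: dosage of the absent minor
                else:
                    c0, c1 = counts[alleles[0]], counts[alleles[1]]
                    minor = alleles[1] if c1 <= c0 else alleles[0]
                    dos[~miss] = ((a1[~miss] == minor).astype(float)
                                  + (a2[~miss] == minor).astype(float))
            marker_rows.append((chrom, mid, float(cm), int(bp)))
            dosage_cols.append(dos)
            mask_cols.append(miss)
    if not marker_rows:
        raise MalformedFileError(f"{tped_path}: no markers")

    markers = pd.DataFrame(marker_rows, columns=MARKER_COLUMNS)
    dosages = np.column_stack(dosage_cols)[keep]
    mask = np.column_stack(mask_cols)[keep]
    samples = tfam.loc[keep, ["fid", "iid", "sex"]].reset_index(drop=True)
    g = GenotypeDataset(dosages, markers, samples, mask)
    y = PhenotypeVector(pheno[keep], family)
    return g, y


def write_tped_tfam(g: GenotypeDataset, y: PhenotypeVector | None,
                    tped_path, tfam_path) -> None:
    """Write a dataset back to TPED/TFAM text.

    Dosages are emitted with allele letters A (major) / C (minor), so a
    subsequent read reproduces the dosage matrix exactly as long as the
    stored coding is minor-allele (frequency <= 0.5, as produced by
    :func:`read_tped_tfam` and the simulator).  Masked entries are
    written as the PLINK missing genotype "0 0".
    """
    geno = {0.0: "A A", 1.0: "A C", 2.0: "C C"}
    mask = g.missing_mask if g.missing_mask is not None else np.zeros_like(
        g.dosages, dtype=bool)
    with open(tped_path, "w") as fh:
        for jcol, row in enumerate(g.markers.itertuples(index=False)):
            parts = [str(row.chrom), str(row.id), f"{row.cm:g}", str(int(row.bp))]
            col = g.dosages[:, jcol]
            cm_ = mask[:, jcol]
            for i in range(g.n):
                if cm_[i] or np.isnan(col[i]):
                    parts.append("0 0")
                else:
                    d = float(np.round(col[i]))
                    if d not in geno:
                        raise ValueError(
                            f"cannot write fractional dosage {col[i]} "
                            f"(marker {row.id}); write pre-imputation data")
                    parts.append(geno[d])
            fh.write(" ".join(parts) + "\n")
    with open(tfam_path, "w") as fh:
        for i, s in enumerate(g.samples.itertuples(index=False)):
            if y is None:
                ph = "-9"
            elif y.family == "logistic":
                ph = "2" if y.values[i] == 1.0 else "1"
            else:
                ph = f"{y.values[i]:g}"
            fh.write(f"{s.fid} {s.iid} 0 0 {s.sex} {ph}\n")


def read_covariates(path, samples: pd.DataFrame) -> CovariateMatrix:
    """Read a headered whitespace table keyed by (FID, IID) columns.

    Rows are aligned to ``samples``; an intercept column is prepended.
    """
    tab = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    cols = list(tab.columns)
    if len(cols) < 3 or cols[0].upper() != "FID" or cols[1].upper() != "IID":
        raise MalformedFileError(
            "covariate file must have header columns FID IID <covariates...>")
    tab = tab.set_index([cols[0], cols[1]])
    key = pd.MultiIndex.from_frame(samples[["fid", "iid"]].astype(str))
    try:
        aligned = tab.loc[key]
    except KeyError as e:
        raise MalformedFileError(f"covariate rows missing for samples: {e}")
    vals = np.column_stack([np.ones(len(samples)),
                            aligned.to_numpy(dtype=float)])
    return CovariateMatrix(vals, ["intercept"] + list(tab.columns))


# ---------------------------------------------------------------------------
# imputation

def impute_missing_mean(g: GenotypeDataset) -> GenotypeDataset:
    """Replace missing entries by each marker's observed mean dosage."""
    if not g.has_missing:
        return g
    mask = g.missing_mask
    n_obs = (~mask).sum(axis=0)
    if np.any(n_obs == 0):
        bad = g.markers["id"].iloc[int(np.argmax(n_obs == 0))]
        raise ValueError(f"marker {bad!r} has no observed genotypes")
    dos = g.dosages.copy()
    dos[mask] = 0.0
    means = dos.sum(axis=0) / n_obs
    out = g.dosages.copy()
    rows, cols = np.nonzero(mask)
    out[rows, cols] = means[cols]
    logger.info("imputed %d missing entries across %d markers",
                mask.sum(), int((mask.any(axis=0)).sum()))
    return GenotypeDataset(out, g.markers, g.samples,
                           np.zeros_like(mask, dtype=bool))


def write_results_table(df: pd.DataFrame, path) -> None:
    """Write a results table as tab-separated text (R-readable)."""
    df.to_csv(path, sep="\t", index=False)
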