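"""Domain types and I/O for female X-linked SNP genotype/trait data.

The estimators in this package operate on a single diallelic X-linked SNP
observed in *n* unrelated females.  Genotypes are expressed as the count of
the designated risk allele ``D`` (0 for dd, 1 for Dd, 2 for DD) and decomposed
into two indicators: ``X1`` (carries at least one ``D``) and ``X2``
(homozygous ``DD``), so that the genotypic value gamma*X1 + (2-gamma)*X2
takes the values {0, gamma, 2}.

Two input representations are supported:

* individual-level delimited text with columns id, genotype, trait and
  optional covariates (required for quantitative traits or covariate models);
* grouped case-control genotype counts (3 genotypes x case/control), which
  are sufficient for qualitative-trait estimation without covariates and
  round-trip losslessly to an expanded individual-level table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_TRAIT_TYPES = ("qualitative", "quantitative")


@dataclass
class XDataset:
    """Female-only genotype/trait/covariate records for one X-linked SNP.

    Attributes
    ----------
    subject_id : array of opaque labels, one per female.
    dosage : integer array in {0, 1, 2}; count of risk (``D``) alleles.
    trait : float array; binary {0, 1} for qualitative traits.
    covariates : (n, M) float array, M >= 0.
    trait_type : "qualitative" or "quantitative".
    """

    subject_id: np.ndarray
    dosage: np.ndarray
    trait: np.ndarray
    covariates: np.ndarray
    trait_type: str

    def __post_init__(self) -> None:
        self.subject_id = np.asarray(self.subject_id)
        self.dosage = np.asarray(self.dosage, dtype=int)
        self.trait = np.asarray(self.trait, dtype=float)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.dosage.shape[0]:
            if self.covariates.size == 0:
                self.covariates = np.empty((self.dosage.shape[0], 0))
            else:
                raise ValueError("covariates row count does not match dosage")
        if self.trait_type not in _VALID_TRAIT_TYPES:
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if not np.isin(self.dosage, (0, 1, 2)).all():
            raise ValueError("dosages must lie in {0, 1, 2}")
        if self.trait_type == "qualitative" and not np.isin(self.trait, (0.0, 1.0)).all():
            raise ValueError("qualitative trait values must be 0 or 1")
        if len(self.trait) != len(self.dosage):
            raise ValueError("trait and dosage lengths differ")

    @property
    def n(self) -> int:
        return int(self.dosage.shape[0])

    @property
    def n_covariates(self) -> int:
        return int(self.covariates.shape[1])

    @classmethod
    def from_grouped_counts(
        cls,
        n_case: tuple[int, int, int],
        n_control: tuple[int, int, int],
    ) -> "XDataset":
        """Expand grouped case-control genotype counts to individual rows.

        ``n_case``/``n_control`` are counts for dosages (0, 1, 2).  Only
        qualitative traits without covariates can be represented this way.
        """
        dosages, traits = [], []
        for y, counts in ((1, n_case), (0, n_control)):
            for dose, count in enumerate(counts):
                if count < 0:
                    raise ValueError("counts must be nonnegative")
                dosages.extend([dose] * int(count))
                traits.extend([y] * int(count))
        n = len(dosages)
        return cls(
            subject_id=np.arange(n),
            dosage=np.array(dosages),
            trait=np.array(traits, dtype=float),
            covariates=np.empty((n, 0)),
            trait_type="qualitative",
        )

    def to_grouped_counts(self) -> tuple[tuple[int, ...], tuple[int, ...]]:
        """Collapse to (case counts, control counts) by dosage (0, 1, 2)."""
        if self.trait_type != "qualitative":
            raise ValueError("grouped representation requires a qualitative trait")
        if self.n_covariates:
            raise ValueError("grouped representation requires no covariates")
        case = tuple(int(((self.dosage == d) & (self.trait == 1)).sum()) for d in range(3))
        ctrl = tuple(int(((self.dosage == d) & (self.trait == 0)).sum()) for d in range(3))
        return case, ctrl

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.subject_id, "genotype": self.dosage, "trait": self.trait})
        for m in range(self.n_covariates):
            df[f"cov{m + 1}"] = self.covariates[:, m]
        return df


@dataclass
class DesignCodes:
    """Indicator decomposition of genotype dosages.

    ``X1[i] = 1`` iff female *i* carries at least one risk allele,
    ``X2[i] = 1`` iff she is homozygous for it; hence X2 <= X1 elementwise.
    """

    X1: np.ndarray
    X2: np.ndarray

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        if self.X1.shape != self.X2.shape:
            raise ValueError("X1 and X2 must have the same shape")
        if np.any(self.X2 > self.X1):
            raise ValueError("X2 = 1 requires X1 = 1")

    def genotypic_value(self, gamma: float) -> np.ndarray:
        """Reconstruct X_i = gamma*X1 + (2-gamma)*X2, i.e. {0, gamma, 2}."""
        return gamma * self.X1 + (2.0 - gamma) * self.X2


def encode(dosage: np.ndarray) -> DesignCodes:
    """Decompose D-allele dosages into the (carrier, homozygote) indicators."""
    dosage = np.asarray(dosage)
    if not np.isin(dosage, (0, 1, 2)).all():
        raise ValueError("dosages must lie in {0, 1, 2}")
    return DesignCodes(X1=(dosage >= 1).astype(float), X2=(dosage == 2).astype(float))


def _dosage_from_genotype(value: object, risk_allele: str) -> int | None:
    """Parse a genotype cell: either a dosage in {0,1,2} or an allele pair."""
    if isinstance(value, (int, np.integer)):
        iv = int(value)
        if iv in (0, 1, 2):
            return iv
        raise ValueError(f"dosage {value!r} outside {{0,1,2}}")
    if isinstance(value, float):
        if np.isnan(value):
            return None
        if float(value).is_integer() and int(value) in (0, 1, 2):
            return int(value)
        raise ValueError(f"dosage {value!r} outside {{0,1,2}}")
    s = str(value).strip()
    if s == "" or s.upper() in ("NA", "NAN", "."):
        return None
    if s in ("0", "1", "2"):
        return int(s)
    if len(s) == 2 and s.isalpha():
        return sum(1 for a in s.upper() if a == risk_allele.upper())
    raise ValueError(f"cannot parse genotype {value!r}")


def read_dataset(
    path,
    trait_type: str,
    risk_allele: str | None = None,
    schema: dict[str, str] | None = None,
    covariate_columns: list[str] | None = None,
    sep: str | None = None,
) -> XDataset:
    """Read an individual-level or grouped-count delimited file.

    A grouped file has columns ``genotype, n_case, n_control`` (one row per
    dosage); an individual file has ``id, genotype, trait`` plus optional
    covariate columns.  ``schema`` remaps column names; ``risk_allele`` is
    required whenever genotypes are allele pairs.  Allele pairs are unordered
    ("TC" and "CT" both give dosage 1 for risk allele T).  Rows with a missing
    genotype or trait are dropped with a logged count.
    """
    if trait_type not in _VALID_TRAIT_TYPES:
        raise ValueError(f"unknown trait_type {trait_type!r}")
    schema = schema or {}
    df = pd.read_csv(path, sep=sep, engine="python")
    df = df.rename(columns={v: k for k, v in schema.items()})

    if "genotype" not in df.columns:
        raise ValueError("missing required columns: ['genotype']")
    needs_allele = df["genotype"].map(
        lambda v: isinstance(v, str) and not v.strip().isdigit()
    ).any()
    if needs_allele and risk_allele is None:
        raise ValueError("risk_allele is required when genotypes are allele pairs")

    if {"n_case", "n_control"} <= set(df.columns):
        if trait_type != "qualitative":
            raise ValueError("grouped counts are only valid for qualitative traits")
        case = [0, 0, 0]
        ctrl = [0, 0, 0]
        for _, row in df.iterrows():
            dose = _dosage_from_genotype(row["genotype"], risk_allele or "")
            if dose is None:
                raise ValueError("grouped file contains an unparseable genotype")
            case[dose] += int(row["n_case"])
            ctrl[dose] += int(row["n_control"])
        return XDataset.from_grouped_counts(tuple(case), tuple(ctrl))

    if "trait" not in df.columns:
        raise ValueError("missing required columns: ['trait']")

    dosages = df["genotype"].map(lambda v: _dosage_from_genotype(v, risk_allele or ""))
    keep = dosages.notna() & df["trait"].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing genotype or trait", n_dropped)
    df = df[keep]
    dosages = dosages[keep].astype(int)

    if covariate_columns is None:
        covariate_columns = [c for c in df.columns if c.startswith("cov")]
    cov = df[covariate_columns].to_numpy(dtype=float) if covariate_columns else np.empty((len(df), 0))

    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    return XDataset(
        subject_id=ids,
        dosage=dosages.to_numpy(),
        trait=df["trait"].to_numpy(dtype=float),
        covariates=cov,
        trait_type=trait_type,
    )


def write_dataset(ds: XDataset, path, sep: str = ",") -> None:
    """Write an individual-level dataset in the same dialect read_dataset reads."""
    ds.to_frame().to_csv(path, sep=sep, index=False)


def write_grouped(ds: XDataset, path, sep: str = ",") -> None:
    """Write grouped case-control counts (qualitative, no covariates)."""
    case, ctrl = ds.to_grouped_counts()
    pd.DataFrame(
        {"genotype": [0, 1, 2], "n_case": list(case), "n_control": list(ctrl)}
    ).to_csv(path, sep=sep, index=False)
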