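"""Radial basis function network over integer-encoded mtDNA genotypes.

The classifier treats each person as a vector of nucleotide codes over a
fixed locus panel (A, G, C, T -> 1, 2, 3, 4; missing -> 0) and computes

    f(x) = b + sum_i  w_i * exp(-||x - M_i||^2 / (2 sigma_i^2))

where the centers M_i are placed by k-means on the training rows, each width
sigma_i is the distance from center i to its nearest other center, and the
weights w_i and bias b are fit by ridge-regularised least squares against
binary targets (1 for the positive study class, 0 for everything else).
Raw f(x) may leave [0, 1]; reported probabilities are clipped, raw scores
are kept for ranking.

The integer code imposes an ordinal artifact (A is numerically closer to G
than to T).  That is a property of the encoding this method is defined over,
and it is kept deliberately; see the methods note for the caveat.

Cohorts are split per class into 2/3 training and 1/3 validation (96 -> 64,
112 -> 75), deterministically for a fixed seed.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: nucleotide -> integer code; 0 is reserved for missing
ENCODING: dict[str, int] = {"A": 1, "G": 2, "C": 3, "T": 4}
DECODING: dict[int, str] = {v: k for k, v in ENCODING.items()}
MISSING_CODE = 0
MISSING_CHAR = "N"

#: center-count grid tried when TrainConfig.m == "auto"
AUTO_M_GRID: tuple[int, ...] = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Cohort-by-locus nucleotide codes with per-sample class labels."""

    sample_ids: tuple[str, ...]
    loci: tuple[int, ...]
    codes: np.ndarray  # (n_samples, n_loci) integers in {0,1,2,3,4}
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2:
            raise ValidationError("codes must be a 2-D array")
        n, p = codes.shape
        if n != len(self.sample_ids) or n != len(self.class_labels):
            raise ValidationError(
                "row count must equal number of sample ids and class labels"
            )
        if p != len(self.loci):
            raise ValidationError("column count must equal number of loci")
        if codes.size and (codes.min() < 0 or codes.max() > 4):
            raise ValidationError("codes must lie in {0,1,2,3,4}")
        object.__setattr__(self, "codes", codes.astype(np.int8, copy=False))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "loci", tuple(int(l) for l in self.loci))
        object.__setattr__(self, "class_labels", tuple(self.class_labels))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.loci == other.loci
            and self.class_labels == other.class_labels
            and np.array_equal(self.codes, other.codes)
        )

    __hash__ = None  # mutable ndarray payload

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        """Panel width — the input dimensionality of the network."""
        return self.codes.shape[1]

    def rows(self) -> np.ndarray:
        return self.codes.astype(float)

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            tuple(self.sample_ids[i] for i in idx),
            self.loci,
            self.codes[idx],
            tuple(self.class_labels[i] for i in idx),
        )


def encode_genotypes(
    raw: pd.DataFrame, class_labels: Sequence[str] | pd.Series
) -> GenotypeMatrix:
    """Encode a sample-by-locus nucleotide table (index = sample ids,
    columns = rCRS loci, cells = single letters).

    Unknown letters (N, gaps, empty cells) become the missing code 0 and are
    counted in a log message.
    """
    labels = list(class_labels)
    if len(labels) != len(raw):
        raise ValidationError("class_labels length must match row count")
    values = raw.to_numpy(dtype=object)
    codes = np.zeros(values.shape, dtype=np.int8)
    unknown = 0
    for (i, j), cell in np.ndenumerate(values):
        letter = str(cell).strip().upper() if cell is not None else ""
        code = ENCODING.get(letter)
        if code is None:
            unknown += 1 if letter not in ("", MISSING_CHAR, "NAN") else 0
            codes[i, j] = MISSING_CODE
        else:
            codes[i, j] = code
    if unknown:
        logger.info("encode_genotypes: %d unknown letter(s) treated as missing", unknown)
    return GenotypeMatrix(
        tuple(str(s) for s in raw.index),
        tuple(int(c) for c in raw.columns),
        codes,
        tuple(labels),
    )


def decode_genotypes(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Inverse of :func:`encode_genotypes`; missing codes render as ``N``."""
    letters = np.vectorize(lambda c: DECODING.get(int(c), MISSING_CHAR))(matrix.codes)
    return pd.DataFrame(letters, index=list(matrix.sample_ids),
                        columns=list(matrix.loci))


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the genotype-matrix TSV: columns ``sample``, ``class``, then one
    column per rCRS locus; cells are single letters."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample", "class"]:
        raise ParseError(f"{path}: expected columns 'sample', 'class', then loci")
    body = df.iloc[:, 2:].copy()
    body.index = df["sample"]
    body.columns = [int(c) for c in body.columns]
    return encode_genotypes(body, df["class"].tolist())


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path,
                       header_lines: Sequence[str] = ()) -> None:
    df = decode_genotypes(matrix)
    df.insert(0, "class", list(matrix.class_labels))
    df.insert(0, "sample", list(matrix.sample_ids))
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs: center count (or "auto" grid search), RNG seed,
    ridge strength, and the training fraction (2/3 by convention)."""

    m: int | str = "auto"
    seed: int = 0
    ridge: float = 1e-6
    train_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        if self.ridge < 0:
            raise ValidationError("ridge must be nonnegative")
        if isinstance(self.m, str):
            if self.m != "auto":
                raise ValidationError("m must be a positive integer or 'auto'")
        elif self.m < 1:
            raise ValidationError("m must be >= 1")


def train_size(n: int, fraction: float = 2.0 / 3.0) -> int:
    """Training-set size for a class of n: fraction rounded to nearest
    (96 -> 64, 112 -> 75, 3 -> 2)."""
    return int(math.floor(n * fraction + 0.5))


def split_train_validation(
    class_labels: Sequence[str], config: TrainConfig | None = None
) -> tuple[list[int], list[int]]:
    """Stratified 2/3-1/3 split; returns (train indices, validation indices).

    Within each class the assignment is a seeded shuffle, so the split is
    deterministic for a fixed seed and a partition of the cohort.
    """
    config = config or TrainConfig()
    labels = list(class_labels)
    rng = np.random.default_rng(config.seed)
    train: list[int] = []
    validation: list[int] = []
    seen: list[str] = []
    for label in labels:
        if label not in seen:
            seen.append(label)
    for label in seen:
        idx = np.array([i for i, l in enumerate(labels) if l == label])
        if len(idx) < 2:
            raise ValidationError(
                f"class {label!r} has {len(idx)} sample(s); need >= 2 to split"
            )
        rng.shuffle(idx)
        k = train_size(len(idx), config.train_fraction)
        k = min(max(k, 1), len(idx) - 1)  # both sides non-empty
        train.extend(int(i) for i in idx[:k])
        validation.extend(int(i) for i in idx[k:])
    return sorted(train), sorted(validation)


@dataclass(frozen=True)
class RBFModel:
    """Fitted network: Gaussian centers/widths plus linear readout."""

    centers: np.ndarray   # (m, n_loci)
    widths: np.ndarray    # (m,) positive
    weights: np.ndarray   # (m,)
    bias: float
    loci: tuple[int, ...]
    positive_class: str = ""

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        widths = np.asarray(self.widths, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != len(self.loci):
            raise ValidationError("centers must be (m, n_loci)")
        m = centers.shape[0]
        if m < 1 or widths.shape != (m,) or weights.shape != (m,):
            raise ValidationError("need m >= 1 centers with matching widths/weights")
        if np.any(widths <= 0):
            raise ValidationError("all widths must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "widths", widths)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "bias", float(self.bias))
        object.__setattr__(self, "loci", tuple(int(l) for l in self.loci))

    @property
    def m(self) -> int:
        return self.centers.shape[0]

    def basis(self, X: np.ndarray) -> np.ndarray:
        """Gaussian activations, shape (n, m)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.loci):
            raise ValidationError(
                f"input has {X.shape[1]} loci, model expects {len(self.loci)}"
            )
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self.widths**2))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Raw weighted sum f(X); may leave [0, 1]."""
        return self.basis(X) @ self.weights + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Clipped probability-like scores in [0, 1]."""
        return np.clip(self.decision_function(X), 0.0, 1.0)

    def nearest_center(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    # --- persistence (versioned JSON; exact float round-trip) -------------

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "mitomatch-rbf",
            "version": 1,
            "encoding": ENCODING,
            "positive_class": self.positive_class,
            "loci": list(self.loci),
            "centers": self.centers.tolist(),
            "widths": self.widths.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RBFModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "mitomatch-rbf":
            raise ParseError(f"{path}: not a saved RBF model")
        if payload.get("version") != 1:
            raise ParseError(f"{path}: unsupported model version")
        return cls(
            centers=np.array(payload["centers"], dtype=float),
            widths=np.array(payload["widths"], dtype=float),
            weights=np.array(payload["weights"], dtype=float),
            bias=float(payload["bias"]),
            loci=tuple(payload["loci"]),
            positive_class=payload.get("positive_class", ""),
        )


def predict(model: RBFModel, x: Sequence[float]) -> float:
    """Probability-like score for one encoded genotype vector."""
    return float(model.predict_proba(np.asarray(x, dtype=float))[0])


def _fit_widths(centers: np.ndarray, X: np.ndarray) -> np.ndarray:
    m = centers.shape[0]
    if m == 1:
        d = np.sqrt(((X - centers[0]) ** 2).sum(axis=1))
        sigma = float(d.mean()) if d.size else 1.0
        return np.array([sigma if sigma > 0 else 1.0])
    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    widths = np.sqrt(d2.min(axis=1))
    fallback = widths[np.isfinite(widths) & (widths > 0)]
    default = float(fallback.mean()) if fallback.size else 1.0
    widths[~(widths > 0)] = default if default > 0 else 1.0
    return widths


def fit_rbf(
    X: np.ndarray, y: np.ndarray, loci: tuple[int, ...], m: int,
    seed: int = 0, ridge: float = 1e-6, positive_class: str = "",
) -> RBFModel:
    """Low-level fit on an explicit design matrix and 0/1 target vector.

    Constant targets are allowed here (the readout then fits the constant);
    :func:`train_rbf` is the cohort-level entry point that enforces the
    presence of both classes."""
    n = X.shape[0]
    if m > n:
        raise ValidationError(f"m={m} exceeds {n} training samples")
    if np.allclose(X, X[0]):
        m = 1  # degenerate: all rows identical
    if m == 1:
        centers = X[:1].copy()
    else:
        km = KMeans(n_clusters=m, random_state=seed, n_init=10)
        with warnings.catch_warnings():
            # cohorts with few distinct genotypes legitimately yield fewer
            # clusters than requested; duplicate centers are handled below
            warnings.simplefilter("ignore", ConvergenceWarning)
            km.fit(X)
        centers = km.cluster_centers_
    widths = _fit_widths(centers, X)
    model0 = RBFModel(centers, widths, np.zeros(m), 0.0, loci, positive_class)
    Phi = np.column_stack([model0.basis(X), np.ones(n)])
    A = Phi.T @ Phi + ridge * np.eye(m + 1)
    coef = np.linalg.solve(A, Phi.T @ y)
    return RBFModel(centers, widths, coef[:m], float(coef[m]), loci, positive_class)


def validation_accuracy(
    model: RBFModel, data: GenotypeMatrix, indices: Sequence[int],
    threshold: float = 0.5,
) -> float:
    """Fraction of the given samples classified correctly at the threshold."""
    idx = list(indices)
    if not idx:
        return float("nan")
    X = data.rows()[idx]
    y = np.array(
        [1.0 if data.class_labels[i] == model.positive_class else 0.0 for i in idx]
    )
    pred = (model.predict_proba(X) > threshold).astype(float)
    return float((pred == y).mean())


def train_rbf(
    data: GenotypeMatrix,
    positive_class: str,
    config: TrainConfig | None = None,
    split: tuple[Sequence[int], Sequence[int]] | None = None,
) -> tuple[RBFModel, tuple[list[int], list[int]]]:
    """Fit the network on the training split of a labelled cohort.

    Targets are 1 for ``positive_class`` and 0 for every other class.  With
    ``m="auto"`` the center count is chosen from :data:`AUTO_M_GRID` by
    validation accuracy (ties -> smaller m).  Returns the model and the
    (train, validation) index lists actually used.
    """
    config = config or TrainConfig()
    if split is None:
        split = split_train_validation(data.class_labels, config)
    train_idx, val_idx = list(split[0]), list(split[1])
    y_train = np.array(
        [1.0 if data.class_labels[i] == positive_class else 0.0 for i in train_idx]
    )
    if y_train.size == 0 or y_train.max() == 0.0:
        raise ValidationError(
            f"no samples of positive class {positive_class!r} in the training split"
        )
    if y_train.min() == 1.0:
        raise ValidationError("training split contains no negative samples")
    X_train = data.rows()[train_idx]

    if config.m == "auto":
        best: tuple[float, int, RBFModel] | None = None
        for m in AUTO_M_GRID:
            if m > len(train_idx):
                continue
            model = fit_rbf(X_train, y_train, data.loci, m,
                                config.seed, config.ridge, positive_class)
            acc = validation_accuracy(model, data, val_idx)
            if best is None or acc > best[0]:
                best = (acc, m, model)
        if best is None:
            raise ValidationError("training set smaller than every grid value of m")
        return best[2], (train_idx, val_idx)

    model = fit_rbf(X_train, y_train, data.loci, int(config.m),
                        config.seed, config.ridge, positive_class)
    return model, (train_idx, val_idx)
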