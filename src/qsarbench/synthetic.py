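"""Synthetic multiclass descriptor tables.

Real QSAR descriptor matrices (a few thousand molecules by a couple of
thousand Dragon-style descriptors, with a multiclass activity label) are
emulated by a low-rank Gaussian mixture: each class is a Gaussian cloud in a
``latent_dim``-dimensional space, class means are placed ``class_separation``
latent noise SDs apart, the latent signal is linearly embedded into the first
``n_informative`` descriptor columns, the remaining columns are pure noise,
and a final mixing operator induces descriptor collinearity.  This gives
datasets whose held-out classification accuracy grows with sample size and
class separation -- the statistical structure the benchmarking harness
assumes -- without any molecular semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: floating-point format used for lossless CSV round-trips
CSV_FLOAT_FORMAT = "%.17g"


class ParameterError(ValueError):
    """An invalid generator or pipeline parameter."""


class DegenerateInputError(ValueError):
    """An input that a stage cannot meaningfully process (e.g. zero-variance
    descriptor column with dropping disabled)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic descriptor dataset.

    Parameters
    ----------
    n_classes:
        Number of classes K (>= 2).
    n_per_class:
        Row count for each class; unequal counts produce an imbalanced table
        so that downstream balancing has work to do.
    n_descriptors:
        Total descriptor columns D.
    n_informative:
        Leading columns that carry the class signal (<= D).
    class_separation:
        Distance between class means in latent space, in units of the latent
        noise SD.  0 means no class signal at all.
    latent_dim:
        Dimension of the low-rank signal space.
    descriptor_noise_sd:
        SD of i.i.d. noise added to every descriptor column on top of the
        embedded signal.
    correlation_strength:
        In [0, 1): how strongly descriptor columns are mixed with each other
        (0 = independent columns).
    noise_df:
        Degrees of freedom of the Student-t descriptor noise; ``None`` gives
        Gaussian noise.  Real descriptor marginals are heavy-tailed and
        outlier-laden, which is what makes normality-and-independence
        assumptions costly on them; the default (3) emulates that.
    seed:
        Master seed; all stage-level randomness is spawned from it.
    """

    n_classes: int = 3
    n_per_class: Sequence[int] = (100, 100, 100)
    n_descriptors: int = 50
    n_informative: int = 20
    class_separation: float = 4.0
    latent_dim: int = 8
    descriptor_noise_sd: float = 1.0
    correlation_strength: float = 0.3
    noise_df: float | None = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ParameterError("n_classes must be >= 2")
        if len(self.n_per_class) != self.n_classes:
            raise ParameterError("n_per_class must have one entry per class")
        if any(int(n) < 1 for n in self.n_per_class):
            raise ParameterError("all class counts must be >= 1")
        if not (1 <= self.n_informative <= self.n_descriptors):
            raise ParameterError("need 1 <= n_informative <= n_descriptors")
        if self.latent_dim < 1:
            raise ParameterError("latent_dim must be >= 1")
        if self.class_separation < 0:
            raise ParameterError("class_separation must be >= 0")
        if self.descriptor_noise_sd < 0:
            raise ParameterError("descriptor_noise_sd must be >= 0")
        if not (0.0 <= self.correlation_strength < 1.0):
            raise ParameterError("correlation_strength must be in [0, 1)")
        if self.noise_df is not None and self.noise_df <= 2:
            raise ParameterError("noise_df must exceed 2 (finite variance) or be None")


@dataclass
class DescriptorTable:
    """An N x D descriptor matrix with sample ids and a class label vector."""

    values: np.ndarray
    sample_ids: list[str]
    descriptor_names: list[str]
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ParameterError("sample_ids/labels length must match row count")
        if len(self.descriptor_names) != d:
            raise ParameterError("descriptor_names length must match column count")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("descriptor values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct class labels, sorted."""
        return np.unique(self.labels)

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def take(self, indices: np.ndarray, metadata: dict | None = None) -> "DescriptorTable":
        """Row subset preserving ids, labels and column names."""
        idx = np.asarray(indices)
        return DescriptorTable(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            descriptor_names=list(self.descriptor_names),
            labels=self.labels[idx],
            metadata={**self.metadata, **(metadata or {})},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DescriptorTable":
        if "sample_id" not in df.columns or "label" not in df.columns:
            raise ParameterError("descriptor CSV needs 'sample_id' and 'label' columns")
        desc = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(
            values=df[desc].to_numpy(dtype=float),
            sample_ids=[str(s) for s in df["sample_id"]],
            descriptor_names=desc,
            labels=df["label"].to_numpy(),
        )

    @classmethod
    def read_csv(cls, path) -> "DescriptorTable":
        # round_trip parser keeps the 17-significant-digit writes lossless
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic counter-based child generator of a master seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _class_means(k: int, latent_dim: int, separation: float,
                 rng: np.random.Generator) -> np.ndarray:
    """K latent means with mean pairwise distance ``separation``."""
    if separation == 0:
        return np.zeros((k, latent_dim))
    raw = rng.standard_normal((k, latent_dim))
    raw -= raw.mean(axis=0, keepdims=True)
    dists = [np.linalg.norm(raw[i] - raw[j]) for i in range(k) for j in range(i + 1, k)]
    scale = separation / np.mean(dists)
    return raw * scale


def generate_dataset(spec: SyntheticSpec) -> DescriptorTable:
    """Draw one synthetic descriptor table from ``spec``.

    Class-conditional distributions are Gaussian in latent space (unit noise
    SD), embedded into the first ``n_informative`` descriptor columns through
    a random linear map; the other columns are pure noise.  Descriptor-level
    noise is Student-t with ``noise_df`` degrees of freedom (heavy-tailed,
    like real descriptor marginals) scaled by ``descriptor_noise_sd``, and
    all columns are mixed by ``(1-rho) I + rho Q`` with Q random orthogonal,
    which induces collinearity of strength ``rho = correlation_strength``.
    Bit-identical output for identical spec (including seed).
    """
    spec.validate()
    n_total = int(sum(spec.n_per_class))
    k, d = spec.n_classes, spec.n_descriptors

    means = _class_means(k, spec.latent_dim, spec.class_separation,
                         _child_rng(spec.seed, 0))

    rng_latent = _child_rng(spec.seed, 1)
    rng_embed = _child_rng(spec.seed, 2)
    rng_noise = _child_rng(spec.seed, 3)
    rng_mix = _child_rng(spec.seed, 4)

    labels = np.repeat(np.arange(k), list(spec.n_per_class))
    latent = rng_latent.standard_normal((n_total, spec.latent_dim)) + means[labels]

    # unit-column embedding keeps the signal scale comparable to the noise
    embed = rng_embed.standard_normal((spec.latent_dim, spec.n_informative))
    embed /= np.linalg.norm(embed, axis=0, keepdims=True)

    if spec.noise_df is None:
        values = rng_noise.standard_normal((n_total, d))
    else:
        values = rng_noise.standard_t(spec.noise_df, size=(n_total, d))
    if spec.descriptor_noise_sd != 1.0:
        values *= spec.descriptor_noise_sd
    values[:, : spec.n_informative] += latent @ embed

    rho = spec.correlation_strength
    if rho > 0:
        q, _ = np.linalg.qr(rng_mix.standard_normal((d, d)))
        values = values @ ((1 - rho) * np.eye(d) + rho * q)

    return DescriptorTable(
        values=values,
        sample_ids=[f"s{i:06d}" for i in range(n_total)],
        descriptor_names=[f"desc{j:04d}" for j in range(d)],
        labels=np.array([f"class{c}" for c in labels]),
        metadata={"spec_seed": spec.seed, "class_separation": spec.class_separation},
    )


def zscore_standardize(table: DescriptorTable,
                       drop_threshold: float | None = 1e-8,
                       ddof: int = 1) -> DescriptorTable:
    """Standardize every descriptor column to mean 0, SD 1 (sample SD, n-1).

    Near-constant columns (centered SD < ``drop_threshold``) are dropped and
    logged; with ``drop_threshold=None`` such a column raises
    :class:`DegenerateInputError` instead.  The SD convention is recorded in
    the output metadata.
    """
    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof) if x.shape[0] > 1 else np.zeros(x.shape[1])

    threshold = drop_threshold if drop_threshold is not None else 0.0
    near_constant = sd < max(threshold, 0.0) if drop_threshold is not None else sd == 0.0
    if near_constant.any():
        dropped = [table.descriptor_names[j] for j in np.flatnonzero(near_constant)]
        if drop_threshold is None:
            raise DegenerateInputError(
                f"zero-variance descriptor column(s) {dropped} with dropping disabled"
            )
        logger.info("dropping %d near-constant descriptor column(s): %s",
                    len(dropped), dropped[:10])

    keep = ~near_constant
    z = (x[:, keep] - mean[keep]) / sd[keep]
    return DescriptorTable(
        values=z,
        sample_ids=list(table.sample_ids),
        descriptor_names=[n for n, k in zip(table.descriptor_names, keep) if k],
        labels=table.labels.copy(),
        metadata={**table.metadata, "zscore_sd_convention": f"sample (ddof={ddof})",
                  "zscore_dropped": int(near_constant.sum())},
    )


__all__ = [
    "SyntheticSpec",
    "DescriptorTable",
    "generate_dataset",
    "zscore_standardize",
    "ParameterError",
    "DegenerateInputError",
    "CSV_FLOAT_FORMAT",
]
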