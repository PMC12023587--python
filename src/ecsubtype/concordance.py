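"""Agreement between two categorical classifiers.

Overall accuracy and Cohen's kappa, with percentile-bootstrap confidence
intervals (paired resampling of samples, 1000 replicates by default).
Kappa corrects the observed agreement p_o for the chance agreement p_e
implied by the two classifiers' marginal label frequencies:

    kappa = (p_o - p_e) / (1 - p_e)

When both classifiers are constant and identical, p_e = 1 and kappa is
defined as 1 (perfect, if vacuous, agreement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["KappaResult", "agreement_stats", "bootstrap_ci", "kappa_with_ci"]


def _encode(labels_a: Sequence, labels_b: Sequence) -> tuple[np.ndarray, np.ndarray, int]:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("empty label vectors")
    alphabet, enc = np.unique(np.concatenate([a, b]), return_inverse=True)
    return enc[: a.size], enc[a.size:], alphabet.size


def _kappa_from_encoded(a: np.ndarray, b: np.ndarray, k: int) -> tuple[float, float]:
    n = a.size
    p_o = float(np.mean(a == b))
    pa = np.bincount(a, minlength=k) / n
    pb = np.bincount(b, minlength=k) / n
    p_e = float(pa @ pb)
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0 if p_o >= 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return p_o, kappa


def agreement_stats(labels_a: Sequence, labels_b: Sequence) -> dict[str, float]:
    """Overall accuracy (observed agreement) and Cohen's kappa."""
    a, b, k = _encode(labels_a, labels_b)
    accuracy, kappa = _kappa_from_encoded(a, b, k)
    return {"accuracy": accuracy, "kappa": kappa}


def bootstrap_ci(
    labels_a: Sequence,
    labels_b: Sequence,
    statistic: str | Callable[[Sequence, Sequence], float] = "kappa",
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile 2.5/97.5 bootstrap bounds over paired resamples.

    ``statistic`` is "kappa", "accuracy", or any callable of two label
    vectors.  Resampling draws sample indices, so the draw sequence (and
    hence the exact bounds) depends on input order; results are fully
    reproducible given ``seed``.  The named statistics use a vectorized
    path; callables fall back to a Python loop.
    """
    a, b, k = _encode(labels_a, labels_b)
    n = a.size
    if n < 2:
        raise ValueError("bootstrap needs at least two samples")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))

    if statistic in ("kappa", "accuracy"):
        A = a[idx]  # (n_boot, n)
        B = b[idx]
        p_o = (A == B).mean(axis=1)
        if statistic == "accuracy":
            stats = p_o
        else:
            p_e = np.zeros(n_boot)
            for label in range(k):
                p_e += (A == label).mean(axis=1) * (B == label).mean(axis=1)
            degen = p_e >= 1.0 - 1e-15
            stats = np.where(
                degen,
                np.where(p_o >= 1.0, 1.0, 0.0),
                (p_o - p_e) / np.where(degen, 1.0, 1.0 - p_e),
            )
    elif callable(statistic):
        raw_a, raw_b = np.asarray(labels_a), np.asarray(labels_b)
        stats = np.array([statistic(raw_a[row], raw_b[row]) for row in idx])
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(lo), float(hi)


@dataclass
class KappaResult:
    """Accuracy and kappa with their bootstrap 95% CIs."""

    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float
    kappa_ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int | None


def kappa_with_ci(
    labels_a: Sequence, labels_b: Sequence, n_boot: int = 1000, seed: int | None = None
) -> KappaResult:
    """Point estimates plus bootstrap CIs for accuracy and kappa.

    Both statistics are resampled from a single RNG stream seeded by
    ``seed`` (accuracy first, then kappa).
    """
    point = agreement_stats(labels_a, labels_b)
    rng_seed = np.random.default_rng(seed)
    acc_seed, kap_seed = (int(s) for s in rng_seed.integers(0, 2**31 - 1, size=2))
    acc_ci = bootstrap_ci(labels_a, labels_b, "accuracy", n_boot=n_boot, seed=acc_seed)
    kap_ci = bootstrap_ci(labels_a, labels_b, "kappa", n_boot=n_boot, seed=kap_seed)
    return KappaResult(
        accuracy=point["accuracy"],
        accuracy_ci=acc_ci,
        kappa=point["kappa"],
        kappa_ci=kap_ci,
        n=len(labels_a),
        n_boot=n_boot,
        seed=seed,
    )
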