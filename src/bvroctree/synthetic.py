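"""Seeded generator of gene-expression-like data with planted signals.

The generator emulates the regime the tree targets — many more genes than
samples, most genes uninformative Gaussian noise — and plants two kinds of
ground-truth structure:

* **planted singles**: a gene whose expression is ``effect * label`` plus
  Gaussian noise (a classic single differentially expressed marker);
* **planted pairs**: two genes sharing a strong latent confounder ``u``
  with opposite loadings, so each gene alone is noisy, while the weighted
  sum ``w1*g1 + w2*g2`` cancels ``u`` and separates the classes by
  ``2*margin`` against only the small private noise.

For a pair with weights ``(w1, w2)``, margin ``m`` and anchor fraction
``f``, the construction is::

    g1 = u            + (f*m/w1)     * label + eps1
    g2 = -(w1/w2) * u + ((1-f)*m/w2) * label + eps2

so ``w1*g1 + w2*g2 = m*label + w1*eps1 + w2*eps2``. The anchor fraction
splits the pair's class signal between the members: ``f = 0.5`` makes both
members equally (and, with a large latent standard deviation, only
marginally) informative, while ``f`` near 1 concentrates the marginal
signal in the first member. The default is asymmetric (``f = 0.87``)
because the tree's greedy node search extends the *best single* gene: a
pair is only discoverable when one member wins the singleton scan against
the noise genes' chance maxima, so the first member is made individually
detectable (population AUC ~0.89, far from separating on its own) while
the partner stays near chance (~0.57). The symmetric setting remains
available to demonstrate exactly the structure the greedy search cannot
reach.

All randomness flows from the single integer seed in the spec through one
``numpy.random.default_rng`` stream; identical specs give byte-identical
matrices.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .exceptions import InputError

__all__ = ["PlantedSingle", "PlantedPair", "SynthSpec", "GroundTruth", "generate"]


@dataclass(frozen=True)
class PlantedSingle:
    """A single informative gene: ``effect * label + N(0, noise_sd)``."""

    gene: int
    effect: float


@dataclass(frozen=True)
class PlantedPair:
    """Two genes whose weighted sum discriminates far better than either alone.

    ``margin`` is half the class separation of the true combination
    ``w1*g1 + w2*g2`` (class means sit at ±margin); ``anchor_fraction``
    splits the marginal class signal between the members (0.5 =
    symmetric); ``latent_sd`` scales the shared confounder that masks
    each member individually.
    """

    genes: tuple[int, int]
    weights: tuple[float, float] = (1.0, 1.0)
    margin: float = 3.0
    anchor_fraction: float = 0.87
    latent_sd: float = 3.0


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic dataset (genes >> samples by default)."""

    n_samples: int = 60
    n_genes: int = 500
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_singles: tuple[PlantedSingle, ...] = ()
    class_balance: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, so tests can assert recovery."""

    pairs: tuple[PlantedPair, ...]
    singles: tuple[PlantedSingle, ...]
    noise_genes: tuple[int, ...]


def default_pair_spec(seed: int = 0, n_samples: int = 60, n_genes: int = 500) -> SynthSpec:
    """The canonical one-planted-pair study condition (anchored pair)."""
    return SynthSpec(
        n_samples=n_samples,
        n_genes=n_genes,
        planted_pairs=(PlantedPair(genes=(17, 271 % n_genes)),),
        seed=seed,
    )


def generate(spec: SynthSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset from ``spec`` (deterministic given the seed).

    Returns the dataset and the planted ground truth. Labels contain
    ``round(class_balance * n_samples)`` positives, shuffled; all
    unplanted genes are i.i.d. standard Gaussian noise.
    """
    n, g = spec.n_samples, spec.n_genes
    if n < 2 or g < 1:
        raise InputError(f"need n_samples >= 2 and n_genes >= 1, got {n}, {g}")
    if not 0.0 < spec.class_balance < 1.0:
        raise InputError("class_balance must lie strictly between 0 and 1")
    if spec.noise_sd <= 0:
        raise InputError("noise_sd must be positive")

    planted: list[int] = []
    for p in spec.planted_pairs:
        if p.margin <= 0 or p.latent_sd <= 0:
            raise InputError("pair margin and latent_sd must be positive")
        if 0 in p.weights:
            raise InputError("pair weights must be non-zero")
        planted.extend(p.genes)
    planted.extend(s.gene for s in spec.planted_singles)
    if len(set(planted)) != len(planted):
        raise InputError("planted gene indices overlap")
    if planted and (min(planted) < 0 or max(planted) >= g):
        raise InputError("planted gene index out of range")

    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.class_balance * n))
    n_pos = min(max(n_pos, 1), n - 1)  # keep both classes present
    y = np.r_[np.ones(n_pos, dtype=np.int8), -np.ones(n - n_pos, dtype=np.int8)]
    rng.shuffle(y)

    X = rng.standard_normal((n, g))
    yf = y.astype(float)
    for p in spec.planted_pairs:
        w1, w2 = p.weights
        c1 = p.anchor_fraction * p.margin / w1
        c2 = (1.0 - p.anchor_fraction) * p.margin / w2
        u = rng.normal(0.0, p.latent_sd, n)
        X[:, p.genes[0]] = u + c1 * yf + rng.normal(0.0, spec.noise_sd, n)
        X[:, p.genes[1]] = -(w1 / w2) * u + c2 * yf + rng.normal(0.0, spec.noise_sd, n)
    for s in spec.planted_singles:
        X[:, s.gene] = s.effect * yf + rng.normal(0.0, spec.noise_sd, n)

    data = Dataset(matrix=X, labels=y)
    truth = GroundTruth(
        pairs=tuple(spec.planted_pairs),
        singles=tuple(spec.planted_singles),
        noise_genes=tuple(j for j in range(g) if j not in set(planted)),
    )
    return data, truth
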