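"""Probabilistic model of biased meiotic segregation of independently
segregating genomic elements (ISEs).

In *Brachionus asplanchnoidis*, Megabase-sized supernumerary elements
segregate during female meiosis without a pairing partner: each of a
mother's ``n`` ISEs ends up either in the haploid egg (which develops
into a male) or in a polar body.  Unbiased segregation sends each ISE to
the egg pole with probability 1/2 independently, so the number of ISEs a
male carries — its genome-size (GS) class — is Binomial(n, 1/2).

Two parameters perturb this null:

``tb`` (transmission bias)
    A per-element drive/drag term.  Each ISE at the egg pole contributes
    a factor ``1 + tb`` to an outcome's weight and each ISE at the polar
    body pole a factor ``1 - tb``.  For a single ISE this gives a
    transmission rate of ``(1 + tb) / 2`` (tb = 0.1 -> 0.55).

``cb`` (cosegregation bias)
    A pairwise interaction: every unordered pair of ISEs on the same
    pole contributes ``1 + cb``; every pair on opposite poles
    contributes ``1 - cb``.  Negative cb ("repulsion") pushes pairs to
    opposite poles, mimicking the behaviour of a regular chromosome
    pair; positive cb makes them travel together.

An outcome (a pole assignment of all n ISEs) has weight equal to the
product of these factors; class frequencies are the normalised weight
mass per number of egg-pole ISEs.  Because the weight depends on an
outcome only through that number k — there are C(k,2) + C(n-k,2)
same-pole pairs and k(n-k) opposite-pole pairs — the distribution has a
closed form; :func:`outcome_weight` remains available as the per-outcome
primitive, and the Monte-Carlo simulator provides an independent check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "IseKaryotype",
    "SegParams",
    "ClassDistribution",
    "OeTable",
    "outcome_weight",
    "class_distribution",
    "unbiased_distribution",
    "oe_ratios",
    "simulate_segregation",
    "male_genome_size",
    "ENUMERATION_CAP",
]

#: Largest n for which exhaustive enumeration over the 2^n pole
#: assignments is permitted (the closed form is O(n) anyway, but the cap
#: keeps `outcome_weight`-based enumeration and simulation honest).
ENUMERATION_CAP = 12

_NORM_TOL = 1e-12


@dataclass(frozen=True)
class SegParams:
    """The (transmission bias, cosegregation bias) parameter pair.

    Both are dimensionless and must lie strictly inside (-1, 1): at
    |cb| = 1 every outcome of three or more ISEs has zero weight, and at
    |tb| = 1 transmission is deterministic.  The fitting grid never
    exceeds +/-0.95.
    """

    tb: float
    cb: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 < self.tb < 1.0):
            raise ValueError(
                f"transmission bias must satisfy -1 < tb < 1, got {self.tb}"
            )
        if not (-1.0 < self.cb < 1.0):
            raise ValueError(
                f"cosegregation bias must satisfy -1 < cb < 1, got {self.cb}"
            )


@dataclass(frozen=True)
class IseKaryotype:
    """A clone's ISE complement and genome sizes.

    The diploid female carries ``n_ise`` unpaired ISEs on top of two
    copies of the core genome, so when both ``core_1c_mb`` and
    ``ise_sizes_mb`` are given the identity
    ``female_2c_mb = 2 * core_1c_mb + sum(ise_sizes_mb)`` must hold.
    Either of the two may be omitted and is then derived from the other.
    """

    n_ise: int
    female_2c_mb: float
    core_1c_mb: Optional[float] = None
    ise_sizes_mb: Optional[tuple] = None
    clone_id: str = ""

    def __post_init__(self) -> None:
        if self.n_ise < 0:
            raise ValueError("n_ise must be >= 0")
        if self.female_2c_mb <= 0:
            raise ValueError("female_2c_mb must be positive")
        if self.ise_sizes_mb is not None:
            sizes = tuple(float(s) for s in self.ise_sizes_mb)
            object.__setattr__(self, "ise_sizes_mb", sizes)
            if len(sizes) != self.n_ise:
                raise ValueError(
                    f"got {len(sizes)} ISE sizes for n_ise={self.n_ise}"
                )
            if any(s <= 0 for s in sizes):
                raise ValueError("all ISE sizes must be positive")
            if self.core_1c_mb is None:
                core = (self.female_2c_mb - sum(sizes)) / 2.0
                if core <= 0:
                    raise ValueError(
                        "ISE sizes exceed female 2C genome size"
                    )
                object.__setattr__(self, "core_1c_mb", core)
            else:
                expect = 2.0 * self.core_1c_mb + sum(sizes)
                if not math.isclose(expect, self.female_2c_mb, rel_tol=1e-6):
                    raise ValueError(
                        "inconsistent karyotype: female_2c_mb must equal "
                        f"2*core_1c_mb + sum(ise_sizes_mb) ({expect:.3f} != "
                        f"{self.female_2c_mb:.3f})"
                    )
        elif self.core_1c_mb is not None:
            if self.core_1c_mb <= 0:
                raise ValueError("core_1c_mb must be positive")
            extra = self.female_2c_mb - 2.0 * self.core_1c_mb
            if self.n_ise > 0 and extra <= 0:
                raise ValueError(
                    "female_2c_mb leaves no room for ISEs above 2*core_1c_mb"
                )

    @property
    def uniform_ise_size_mb(self) -> float:
        """Per-ISE size assumed when individual sizes are unknown."""
        if self.n_ise == 0:
            return 0.0
        if self.core_1c_mb is None:
            raise ValueError("need core_1c_mb or ise_sizes_mb")
        return (self.female_2c_mb - 2.0 * self.core_1c_mb) / self.n_ise

    def sizes(self) -> tuple:
        if self.ise_sizes_mb is not None:
            return self.ise_sizes_mb
        return (self.uniform_ise_size_mb,) * self.n_ise


@dataclass(frozen=True)
class ClassDistribution:
    """Relative frequencies of male GS classes k = 0..n_ise.

    ``freqs[k]`` is the probability that a male carries exactly k ISEs.
    Frequencies are nonnegative and sum to one.
    """

    n_ise: int
    freqs: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (self.n_ise + 1,):
            raise ValueError(
                f"expected {self.n_ise + 1} class frequencies, got {f.shape}"
            )
        if np.any(f < -_NORM_TOL):
            raise ValueError("class frequencies must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class frequencies must sum to 1, got {f.sum()!r}"
            )

    @property
    def mean_classes(self) -> float:
        """Expected number of ISEs transmitted to a male."""
        return float(np.arange(self.n_ise + 1) @ self.freqs)


@dataclass(frozen=True)
class OeTable:
    """Per-class observed/expected comparison.

    ``ratio[k] = observed[k] / expected[k]`` where the expectation is
    positive; classes with zero expected mass carry NaN and are flagged
    in ``undefined``.
    """

    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray
    undefined: np.ndarray

    def __len__(self) -> int:
        return len(self.ratio)


def _validate_params(params: SegParams) -> SegParams:
    if not isinstance(params, SegParams):
        params = SegParams(*params)
    return params


def outcome_weight(poles: Sequence[str], params: SegParams) -> float:
    """Unnormalised weight of one pole assignment of all ISEs.

    ``poles`` lists, per ISE, the pole it migrated to: ``"egg"`` or
    ``"polar"``.  The weight multiplies one marginal factor per ISE
    (``1+tb`` egg, ``1-tb`` polar body) and one interaction factor per
    unordered pair (``1+cb`` same pole, ``1-cb`` opposite poles).
    """
    params = _validate_params(params)
    for p in poles:
        if p not in ("egg", "polar"):
            raise ValueError(f"pole must be 'egg' or 'polar', got {p!r}")
    egg = sum(1 for p in poles if p == "egg")
    n = len(poles)
    return _class_weight(n, egg, params.tb, params.cb)


def _class_weight(n: int, k: int, tb: float, cb: float) -> float:
    """Weight of any single outcome with k of n ISEs at the egg pole."""
    same = k * (k - 1) // 2 + (n - k) * (n - k - 1) // 2
    opposite = k * (n - k)
    return (
        (1.0 + tb) ** k
        * (1.0 - tb) ** (n - k)
        * (1.0 + cb) ** same
        * (1.0 - cb) ** opposite
    )


def class_distribution(n_ise: int, params: SegParams) -> ClassDistribution:
    """Predicted relative frequencies of the male GS classes.

    Enumerates the 2^n equally-likely pole assignments, weights each by
    :func:`outcome_weight` and normalises; collapsing outcomes by their
    egg-pole count k gives ``freq_k proportional to C(n, k) * w(n, k)``.
    With cb = 0 this reduces to Binomial(n, (1+tb)/2); with tb = 0 it is
    symmetric in k <-> n-k.
    """
    params = _validate_params(params)
    if n_ise < 0:
        raise ValueError("n_ise must be >= 0")
    if n_ise > ENUMERATION_CAP:
        raise ValueError(
            f"n_ise={n_ise} exceeds the enumeration cap of "
            f"{ENUMERATION_CAP}; use simulate_segregation for a "
            "Monte-Carlo approximation"
        )
    k = np.arange(n_ise + 1)
    mult = np.array([math.comb(n_ise, int(j)) for j in k], dtype=float)
    w = np.array(
        [_class_weight(n_ise, int(j), params.tb, params.cb) for j in k]
    )
    mass = mult * w
    total = mass.sum()
    if total <= 0:
        raise ValueError("degenerate parameters: total outcome weight is 0")
    return ClassDistribution(n_ise=n_ise, freqs=mass / total)


def unbiased_distribution(n_ise: int) -> ClassDistribution:
    """Binomial(n, 1/2) class frequencies expected under random segregation."""
    if n_ise < 0:
        raise ValueError("n_ise must be >= 0")
    k = np.arange(n_ise + 1)
    f = np.array([math.comb(n_ise, int(j)) for j in k], dtype=float)
    return ClassDistribution(n_ise=n_ise, freqs=f / 2.0 ** n_ise)


def oe_ratios(observed: ClassDistribution, expected: ClassDistribution) -> OeTable:
    """Observed/expected ratio per GS class.

    O/E = 1 everywhere under unbiased transmission; O/E > 1 flags an
    overrepresented class.  Classes with zero expected frequency are
    flagged undefined rather than divided.
    """
    if observed.n_ise != expected.n_ise:
        raise ValueError(
            f"class counts differ: observed has {observed.n_ise + 1}, "
            f"expected has {expected.n_ise + 1}"
        )
    obs = observed.freqs
    exp = expected.freqs
    undefined = exp <= 0.0
    ratio = np.full_like(obs, np.nan)
    np.divide(obs, exp, out=ratio, where=~undefined)
    return OeTable(observed=obs, expected=exp, ratio=ratio, undefined=undefined)


def simulate_segregation(
    n_ise: int,
    params: SegParams,
    n_males: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo draw of GS-class counts for ``n_males`` males.

    Samples outcomes from the same weighted law as
    :func:`class_distribution` (multinomially, since males are
    independent meioses); serves as an independent stochastic oracle for
    the enumeration.  Identical seeds give identical counts.
    """
    if n_males < 1:
        raise ValueError("n_males must be >= 1")
    dist = class_distribution(n_ise, params)
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_males, dist.freqs)


def male_genome_size(
    k: int,
    karyotype: IseKaryotype,
    carried: Optional[Sequence[int]] = None,
) -> tuple[float, float]:
    """Genome size of a male in GS class k.

    Returns ``(absolute Mb, fraction of the female 2C)``.  ``carried``
    optionally names the indices of the k ISEs the male inherited (the
    classes of a clone with unequal ISE sizes overlap in genome size);
    without it the first k sizes are used, which for the uniform-size
    convention is exact.
    """
    if not (0 <= k <= karyotype.n_ise):
        raise ValueError(f"class index k={k} outside 0..{karyotype.n_ise}")
    if karyotype.core_1c_mb is None:
        raise ValueError("karyotype needs core_1c_mb or ise_sizes_mb")
    sizes = karyotype.sizes()
    if carried is not None:
        carried = list(carried)
        if len(carried) != k:
            raise ValueError(
                f"carried lists {len(carried)} ISEs but k={k}"
            )
        total = sum(sizes[i] for i in carried)
    else:
        total = sum(sizes[:k])
    absolute = karyotype.core_1c_mb + total
    return absolute, absolute / karyotype.female_2c_mb
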