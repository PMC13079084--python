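"""End-member mixing analysis with Monte Carlo uncertainty propagation.

A mixture is un-mixed into k sources using k-1 conservative tracers plus the
mass-balance closure (fractions sum to 1). Two conceptual models are
supported:

* ``equilibration`` — three sources (e.g. peat, modern, atmosphere) and two
  tracers (d13C and F14C); appropriate when the dissolved pool exchanges
  with the atmosphere.
* ``outgassing`` — two sources and F14C only; appropriate when strong CO2
  evasion prevents atmospheric equilibration and kinetic fractionation makes
  d13C non-conservative (F14C is fractionation-corrected by definition).

Uncertainty is propagated by rejection sampling: every tracer value (sources
and mixture) is redrawn from its normal distribution each iteration, the
linear system is solved exactly, and only solutions with all fractions in
the closed interval [0, 1] are retained. The two models' peat estimates are
then pooled by inverse-variance weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "TRACERS_BY_MODEL",
    "EndMember",
    "MixtureObs",
    "MixingProblem",
    "PosteriorSummary",
    "CombinedEstimate",
    "SingularSystemError",
    "ZeroAcceptanceError",
    "solve_exact",
    "run_monte_carlo",
    "combine_inverse_variance",
    "consistency_check",
]

#: Tracers used by each conceptual model, in draw order.
TRACERS_BY_MODEL: dict[str, tuple[str, ...]] = {
    "equilibration": ("d13c", "f14c"),
    "outgassing": ("f14c",),
}

#: Determinant threshold (relative to matrix scale) below which a drawn
#: system is treated as singular and the draw rejected.
_SINGULAR_RTOL = 1e-12


class SingularSystemError(ValueError):
    """The end-member design matrix is singular or near-singular."""


class ZeroAcceptanceError(RuntimeError):
    """No Monte Carlo draw produced fractions inside [0, 1]."""


def _check_tracer_pair(mean: float, sd: float, what: str, tracer: str) -> None:
    if not np.isfinite(mean):
        raise ValueError(f"{what}: {tracer} mean must be finite, got {mean}")
    if not (sd >= 0):
        raise ValueError(f"{what}: {tracer} sd must be >= 0, got {sd}")


@dataclass(frozen=True)
class EndMember:
    """A named source with per-tracer mean and standard deviation.

    d13C in permil VPDB; F14C dimensionless (fraction modern, must be
    positive).
    """

    name: str
    d13c_mean: float
    d13c_sd: float
    f14c_mean: float
    f14c_sd: float

    def __post_init__(self) -> None:
        _check_tracer_pair(self.d13c_mean, self.d13c_sd, self.name, "d13c")
        _check_tracer_pair(self.f14c_mean, self.f14c_sd, self.name, "f14c")
        if not (self.f14c_mean > 0):
            raise ValueError(
                f"{self.name}: f14c_mean must be > 0, got {self.f14c_mean}"
            )


@dataclass(frozen=True)
class MixtureObs:
    """The observed mixture (e.g. a water body's DIC pool)."""

    d13c_mean: float
    d13c_sd: float
    f14c_mean: float
    f14c_sd: float
    label: str = "mixture"

    def __post_init__(self) -> None:
        _check_tracer_pair(self.d13c_mean, self.d13c_sd, self.label, "d13c")
        _check_tracer_pair(self.f14c_mean, self.f14c_sd, self.label, "f14c")
        if not (self.f14c_mean > 0):
            raise ValueError(
                f"{self.label}: f14c_mean must be > 0, got {self.f14c_mean}"
            )


@dataclass(frozen=True)
class MixingProblem:
    """One un-mixing problem: model choice, ordered sources, and mixture.

    ``equilibration`` requires exactly 3 sources (2 tracers: d13c, f14c);
    ``outgassing`` exactly 2 sources (1 tracer: f14c).
    """

    model: Literal["equilibration", "outgassing"]
    sources: tuple[EndMember, ...]
    mixture: MixtureObs

    def __post_init__(self) -> None:
        if self.model not in TRACERS_BY_MODEL:
            raise ValueError(
                f"unknown model {self.model!r}; expected one of "
                f"{sorted(TRACERS_BY_MODEL)}"
            )
        object.__setattr__(self, "sources", tuple(self.sources))
        expected = len(self.tracers) + 1
        if len(self.sources) != expected:
            raise ValueError(
                f"{self.model} model requires exactly {expected} sources, "
                f"got {len(self.sources)}"
            )
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate source names: {names}")

    @property
    def tracers(self) -> tuple[str, ...]:
        return TRACERS_BY_MODEL[self.model]

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sources)

    def source_means(self) -> np.ndarray:
        """(k, k-1) array of source tracer means, rows = sources."""
        return np.array(
            [[getattr(s, f"{t}_mean") for t in self.tracers] for s in self.sources]
        )

    def source_sds(self) -> np.ndarray:
        return np.array(
            [[getattr(s, f"{t}_sd") for t in self.tracers] for s in self.sources]
        )

    def mixture_means(self) -> np.ndarray:
        return np.array([getattr(self.mixture, f"{t}_mean") for t in self.tracers])

    def mixture_sds(self) -> np.ndarray:
        return np.array([getattr(self.mixture, f"{t}_sd") for t in self.tracers])


@dataclass(frozen=True)
class PosteriorSummary:
    """Accepted Monte Carlo fraction samples and their summary statistics.

    ``samples`` has one row per accepted draw, one column per source (in
    ``source_names`` order); every row sums to 1 and lies in [0, 1]^k.
    ``raw_fractions`` (only with ``keep_raw=True``) additionally holds every
    solved draw, NaN rows marking singular systems, so the rejection filter
    can be independently re-applied.
    """

    source_names: tuple[str, ...]
    samples: np.ndarray
    fractions_mean: np.ndarray
    fractions_sd: np.ndarray
    n_iter: int
    n_accepted: int
    acceptance_rate: float
    seed: object = None
    model: str | None = None
    raw_fractions: np.ndarray | None = field(default=None, repr=False)

    def _index(self, source: str) -> int:
        try:
            return self.source_names.index(source)
        except ValueError:
            raise KeyError(
                f"source {source!r} not in {self.source_names}"
            ) from None

    def mean(self, source: str) -> float:
        return float(self.fractions_mean[self._index(source)])

    def sd(self, source: str) -> float:
        return float(self.fractions_sd[self._index(source)])

    def as_dict(self) -> dict:
        """JSON-friendly summary (samples omitted)."""
        return {
            "model": self.model,
            "sources": list(self.source_names),
            "fractions_mean": {
                n: float(m) for n, m in zip(self.source_names, self.fractions_mean)
            },
            "fractions_sd": {
                n: float(s) for n, s in zip(self.source_names, self.fractions_sd)
            },
            "n_iter": self.n_iter,
            "n_accepted": self.n_accepted,
            "acceptance_rate": self.acceptance_rate,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CombinedEstimate:
    """Inverse-variance weighted combination of two posterior estimates."""

    source: str
    mean: float
    sd: float
    weights: dict[str, float]
    components: tuple[PosteriorSummary, PosteriorSummary]
    mode: str = "pooled_variance"

    def as_dict(self) -> dict:
        return {
            "source": self.source,
            "mean": self.mean,
            "sd": self.sd,
            "weights": dict(self.weights),
            "mode": self.mode,
        }


def solve_exact(
    source_tracers: np.ndarray,
    mixture_tracers: np.ndarray,
    source_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Solve the linear un-mixing system exactly for one tracer realisation.

    For k sources and k-1 tracers, solves::

        [ tracer rows (k-1 x k) ]       [ mixture tracers ]
        [ ones row              ] @ f = [ 1               ]

    Parameters
    ----------
    source_tracers
        (k, k-1) array; row i holds source i's tracer values.
    mixture_tracers
        (k-1,) array of the mixture's tracer values.
    source_names
        Optional labels used in the singular-system error message.

    Returns
    -------
    numpy.ndarray
        The unique fraction vector ``f``. It sums to 1 by construction but
        is NOT clamped to [0, 1] — infeasible mixtures yield fractions
        outside that range.

    Raises
    ------
    SingularSystemError
        If the design matrix is singular or near-singular (collinear
        end-members), naming the offending sources.
    """
    S = np.asarray(source_tracers, dtype=float)
    m = np.atleast_1d(np.asarray(mixture_tracers, dtype=float))
    if S.ndim == 1:
        S = S[:, None]
    k = S.shape[0]
    if S.shape[1] != k - 1 or m.shape[0] != k - 1:
        raise ValueError(
            f"need k-1 tracers for k={k} sources; got source block "
            f"{S.shape} and mixture {m.shape}"
        )
    A = np.vstack([S.T, np.ones(k)])
    b = np.concatenate([m, [1.0]])
    scale = max(float(np.abs(A).max()), 1.0) ** k
    if abs(np.linalg.det(A)) <= _SINGULAR_RTOL * scale:
        names = tuple(source_names) if source_names is not None else tuple(
            f"source_{i}" for i in range(k)
        )
        raise SingularSystemError(
            f"end-member design matrix is singular: sources {names} are "
            f"collinear in tracer space"
        )
    return np.linalg.solve(A, b)


def run_monte_carlo(
    problem: MixingProblem,
    n_iter: int = 100_000,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    keep_raw: bool = False,
) -> PosteriorSummary:
    """Propagate tracer uncertainty through the un-mixing by rejection sampling.

    Each iteration independently redraws every source tracer and every
    mixture tracer from Normal(mean, sd) (draws are NOT truncated), solves
    the linear system, and retains the draw iff all fractions lie in the
    closed interval [0, 1]. Draws producing a singular system count as
    rejected. Summary statistics are computed over retained draws only
    (sample s.d., n-1 denominator).

    Reproducible: identical (problem, n_iter, seed) gives a bit-identical
    result.

    Raises
    ------
    ZeroAcceptanceError
        If no draw is accepted; the message reports the most frequently
        violated constraint.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    k = len(problem.sources)
    t = k - 1

    # Draw order is fixed: all source tracers first, then mixture tracers.
    src = rng.normal(problem.source_means(), problem.source_sds(), size=(n_iter, k, t))
    mix = rng.normal(problem.mixture_means(), problem.mixture_sds(), size=(n_iter, t))

    A = np.empty((n_iter, k, k))
    A[:, :t, :] = np.swapaxes(src, 1, 2)
    A[:, t, :] = 1.0
    b = np.empty((n_iter, k))
    b[:, :t] = mix
    b[:, t] = 1.0

    det = np.linalg.det(A)
    scale = np.maximum(np.abs(A).max(axis=(1, 2)), 1.0) ** k
    solvable = np.abs(det) > _SINGULAR_RTOL * scale

    fractions = np.full((n_iter, k), np.nan)
    if solvable.any():
        fractions[solvable] = np.linalg.solve(
            A[solvable], b[solvable][:, :, None]
        )[:, :, 0]

    inside = solvable & (fractions >= 0.0).all(axis=1) & (fractions <= 1.0).all(axis=1)
    n_accepted = int(inside.sum())

    if n_accepted == 0:
        raise ZeroAcceptanceError(
            "no accepted draws (acceptance_rate 0.0 over "
            f"{n_iter} iterations); most-violated constraint: "
            + _most_violated(problem, fractions, solvable)
        )

    samples = fractions[inside]
    if n_accepted == 1 or (samples == samples[0]).all():
        # degenerate (all-identical) posteriors stay exactly equal to the
        # single solution; naive averaging would round at the ULP level
        mean = samples[0].copy()
        sd = np.zeros(k)
    else:
        mean = samples.mean(axis=0)
        sd = samples.std(axis=0, ddof=1)
    seed_record = seed if isinstance(seed, (int, type(None))) else repr(seed)
    return PosteriorSummary(
        source_names=problem.source_names,
        samples=samples,
        fractions_mean=mean,
        fractions_sd=sd,
        n_iter=n_iter,
        n_accepted=n_accepted,
        acceptance_rate=n_accepted / n_iter,
        seed=seed_record,
        model=problem.model,
        raw_fractions=fractions if keep_raw else None,
    )


def _most_violated(
    problem: MixingProblem, fractions: np.ndarray, solvable: np.ndarray
) -> str:
    if not solvable.any():
        return "all drawn systems were singular"
    f = fractions[solvable]
    worst, desc = -1, "unknown"
    for j, name in enumerate(problem.source_names):
        for cnt, what in ((int((f[:, j] < 0).sum()), "< 0"),
                          (int((f[:, j] > 1).sum()), "> 1")):
            if cnt > worst:
                worst, desc = cnt, f"f[{name}] {what} in {cnt}/{len(f)} solved draws"
    return desc


def _validate_pair(
    a: PosteriorSummary, b: PosteriorSummary, source: str, strict_sd: bool = True
) -> tuple[float, float, float, float]:
    m_a, s_a = a.mean(source), a.sd(source)
    m_b, s_b = b.mean(source), b.sd(source)
    if strict_sd and (s_a <= 0 or s_b <= 0):
        raise ValueError(
            f"posterior sd for {source!r} must be > 0 in both models "
            f"(got {s_a} and {s_b}); inverse-variance weight undefined"
        )
    return m_a, s_a, m_b, s_b


def combine_inverse_variance(
    a: PosteriorSummary,
    b: PosteriorSummary,
    source: str = "peat",
    mode: str = "pooled_variance",
) -> CombinedEstimate:
    """Pool two models' estimates of one source fraction by inverse variance.

    mean = (m_a/s_a^2 + m_b/s_b^2) / (1/s_a^2 + 1/s_b^2).

    ``mode`` controls the combined s.d.:

    * ``"pooled_variance"`` (default): sd = sqrt(1 / (1/s_a^2 + 1/s_b^2)),
      standard inverse-variance pooling.
    * ``"pooled_posterior"``: s.d. of the inverse-variance-weighted mixture
      of the two posteriors (computed in closed form from the component
      moments); larger when the means disagree.
    """
    m_a, s_a, m_b, s_b = _validate_pair(a, b, source)
    w_a, w_b = 1.0 / s_a**2, 1.0 / s_b**2
    mean = (m_a * w_a + m_b * w_b) / (w_a + w_b)
    if mode == "pooled_variance":
        sd = float(np.sqrt(1.0 / (w_a + w_b)))
    elif mode == "pooled_posterior":
        p_a = w_a / (w_a + w_b)
        p_b = 1.0 - p_a
        second = p_a * (s_a**2 + m_a**2) + p_b * (s_b**2 + m_b**2)
        sd = float(np.sqrt(second - mean**2))
    else:
        raise ValueError(
            f"mode must be 'pooled_variance' or 'pooled_posterior', got {mode!r}"
        )
    model_key = lambda s, tag: s.model or tag  # noqa: E731
    return CombinedEstimate(
        source=source,
        mean=float(mean),
        sd=sd,
        weights={model_key(a, "a"): float(w_a), model_key(b, "b"): float(w_b)},
        components=(a, b),
        mode=mode,
    )


def consistency_check(
    a: PosteriorSummary,
    b: PosteriorSummary,
    source: str = "peat",
    k: float = 1.0,
) -> tuple[bool, dict]:
    """Are two models' estimates of a source fraction statistically consistent?

    True iff |m_a - m_b| <= k * sqrt(s_a^2 + s_b^2). Returns the verdict and
    a report of the quantities entering it. Zero sds are tolerated here
    (degenerate posteriors are compared by exact equality of means).
    """
    m_a, s_a, m_b, s_b = _validate_pair(a, b, source, strict_sd=False)
    diff = abs(m_a - m_b)
    threshold = k * float(np.sqrt(s_a**2 + s_b**2))
    consistent = diff <= threshold
    report = {
        "source": source,
        "mean_a": m_a,
        "sd_a": s_a,
        "mean_b": m_b,
        "sd_b": s_b,
        "abs_difference": diff,
        "threshold": threshold,
        "k": k,
        "consistent": consistent,
    }
    return consistent, report
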