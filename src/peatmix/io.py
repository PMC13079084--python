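"""Measurement tables, run configuration, and the end-to-end analysis driver.

The measurement table is a plain CSV (comma-separated, UTF-8, header
required, missing values as empty cells) with columns::

    site,pool,replicate,d13c,f14c[,conc][,depth]

``pool`` is one of DIC, DOC, POC, SOC, ATM; d13c in permil VPDB, f14c
dimensionless fraction modern, conc in any consistent concentration unit,
depth in m. Units are fixed by the schema, never per-file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from peatmix.flux import annual_carbon_mass
from peatmix.mixing import (
    CombinedEstimate,
    EndMember,
    MixingProblem,
    MixtureObs,
    PosteriorSummary,
    ZeroAcceptanceError,
    combine_inverse_variance,
    consistency_check,
    run_monte_carlo,
)

__all__ = [
    "POOLS",
    "PoolMeasurement",
    "PoolSummary",
    "read_measurement_table",
    "write_measurement_table",
    "summarize_pools",
    "run_models",
    "analyze_dataset",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

#: Closed vocabulary of measurable carbon pools.
POOLS = ("DIC", "DOC", "POC", "SOC", "ATM")

#: Which measurement pool stands in for each mixing source by default.
DEFAULT_SOURCE_POOLS: dict[str, str] = {
    "peat": "SOC",
    "modern": "DOC",
    "atmosphere": "ATM",
}

_MODEL_ORDER = ("equilibration", "outgassing")
_REQUIRED_COLUMNS = ("site", "pool", "replicate", "d13c", "f14c")


@dataclass(frozen=True)
class PoolMeasurement:
    """One isotopic observation of a carbon pool."""

    site: str
    pool: str
    replicate: int
    d13c: float
    f14c: float
    conc: float | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise ValueError(
                f"unknown pool {self.pool!r}; expected one of {POOLS}"
            )
        if not (self.f14c > 0):
            raise ValueError(f"f14c must be > 0, got {self.f14c}")


@dataclass(frozen=True)
class PoolSummary:
    """Per-(site, pool) tracer summary: mean and sample s.d. (n-1).

    ``d13c_sd``/``f14c_sd`` are ``None`` for single-replicate groups.
    """

    site: str
    pool: str
    n: int
    d13c_mean: float
    d13c_sd: float | None
    f14c_mean: float
    f14c_sd: float | None
    conc_mean: float | None = None


def read_measurement_table(path: str | Path) -> list[PoolMeasurement]:
    """Read and validate a measurement CSV.

    Raises
    ------
    ValueError
        On missing required columns, an empty table, non-numeric tracer
        values, or out-of-vocabulary pools — always naming the offending
        row (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: table contains no data rows")
    records: list[PoolMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pool = str(row.pool)
        if pool not in POOLS:
            raise ValueError(
                f"{path}: row {i}: unknown pool {pool!r}; expected one of {POOLS}"
            )
        try:
            d13c = float(row.d13c)
            f14c = float(row.f14c)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: row {i}: non-numeric tracer value "
                f"(d13c={row.d13c!r}, f14c={row.f14c!r})"
            ) from exc
        if np.isnan(d13c) or np.isnan(f14c):
            raise ValueError(f"{path}: row {i}: missing tracer value")
        conc = getattr(row, "conc", None)
        depth = getattr(row, "depth", None)
        records.append(
            PoolMeasurement(
                site=str(row.site),
                pool=pool,
                replicate=int(row.replicate),
                d13c=d13c,
                f14c=f14c,
                conc=None if conc is None or pd.isna(conc) else float(conc),
                depth=None if depth is None or pd.isna(depth) else float(depth),
            )
        )
    return records


def write_measurement_table(
    records: Iterable[PoolMeasurement], path: str | Path
) -> None:
    """Write measurements to CSV in the documented schema (round-trips with
    :func:`read_measurement_table`)."""
    df = pd.DataFrame(
        [
            {
                "site": r.site,
                "pool": r.pool,
                "replicate": r.replicate,
                "d13c": repr(r.d13c),
                "f14c": repr(r.f14c),
                "conc": "" if r.conc is None else repr(r.conc),
                "depth": "" if r.depth is None else repr(r.depth),
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def summarize_pools(
    records: Sequence[PoolMeasurement],
) -> dict[tuple[str, str], PoolSummary]:
    """Per-(site, pool) mean and sample s.d. (n-1 denominator) of each tracer."""
    if not records:
        raise ValueError("no measurement records to summarize")
    groups: dict[tuple[str, str], list[PoolMeasurement]] = {}
    for r in records:
        groups.setdefault((r.site, r.pool), []).append(r)
    out = {}
    for key, rows in groups.items():
        d13c = np.array([r.d13c for r in rows])
        f14c = np.array([r.f14c for r in rows])
        conc = [r.conc for r in rows if r.conc is not None]
        n = len(rows)
        out[key] = PoolSummary(
            site=key[0],
            pool=key[1],
            n=n,
            d13c_mean=float(d13c.mean()),
            d13c_sd=float(d13c.std(ddof=1)) if n > 1 else None,
            f14c_mean=float(f14c.mean()),
            f14c_sd=float(f14c.std(ddof=1)) if n > 1 else None,
            conc_mean=float(np.mean(conc)) if conc else None,
        )
    return out


def _summary_to_end_member(name: str, s: PoolSummary) -> EndMember:
    if s.d13c_sd is None or s.f14c_sd is None:
        raise ValueError(
            f"({s.site}, {s.pool}): single replicate; cannot define "
            f"end member {name!r} without a spread"
        )
    return EndMember(
        name=name,
        d13c_mean=s.d13c_mean,
        d13c_sd=s.d13c_sd,
        f14c_mean=s.f14c_mean,
        f14c_sd=s.f14c_sd,
    )


def _seed_for_models(
    seed: int | np.random.SeedSequence | None, models: Sequence[str]
) -> dict[str, np.random.SeedSequence]:
    """One independent child seed per model, in fixed model order."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(
        seed
    )
    ordered = [m for m in _MODEL_ORDER if m in models]
    return dict(zip(ordered, ss.spawn(len(ordered))))


def run_models(
    problems: Mapping[str, MixingProblem],
    n_iter: int = 100_000,
    seed: int | np.random.SeedSequence | None = None,
    source: str = "peat",
    combine_mode: str = "pooled_variance",
    consistency_k: float = 1.0,
) -> dict:
    """Run one or both mixing models and, when both, check consistency and
    combine the named source's estimates by inverse variance.

    Returns a dict with keys ``posteriors`` (model -> PosteriorSummary) and,
    when two models ran, ``consistency`` (report dict) and ``combined``
    (CombinedEstimate).
    """
    seeds = _seed_for_models(seed, list(problems))
    posteriors: dict[str, PosteriorSummary] = {}
    for model in seeds:
        posteriors[model] = run_monte_carlo(
            problems[model], n_iter=n_iter, seed=seeds[model]
        )
        logger.info(
            "%s model: acceptance_rate=%.4f",
            model, posteriors[model].acceptance_rate,
        )
    result: dict = {"posteriors": posteriors}
    if len(posteriors) == 2:
        a, b = (posteriors[m] for m in posteriors)
        _, report = consistency_check(a, b, source=source, k=consistency_k)
        result["consistency"] = report
        s_a, s_b = a.sd(source), b.sd(source)
        if s_a == 0.0 or s_b == 0.0:
            # a zero-spread posterior is exact: the s -> 0 limit of
            # inverse-variance weighting puts all weight on it
            m_a, m_b = a.mean(source), b.mean(source)
            if s_a == 0.0 and s_b == 0.0:
                # both point masses: they must agree (up to solver round-off)
                if abs(m_a - m_b) > 1e-9 * max(1.0, abs(m_a)):
                    raise ValueError(
                        f"both posteriors for {source!r} are degenerate but "
                        f"disagree: {m_a} vs {m_b}"
                    )
                mean = 0.5 * (m_a + m_b)
            else:
                mean = m_a if s_a == 0.0 else m_b
            result["combined"] = CombinedEstimate(
                source=source,
                mean=mean,
                sd=0.0,
                weights={},
                components=(a, b),
                mode="degenerate",
            )
        else:
            result["combined"] = combine_inverse_variance(
                a, b, source=source, mode=combine_mode
            )
    return result


def build_problems(
    end_members: Mapping[str, EndMember],
    mixture: MixtureObs,
    models: Sequence[str],
) -> dict[str, MixingProblem]:
    """Assemble MixingProblems from named end members.

    ``equilibration`` uses (peat, modern, atmosphere); ``outgassing`` uses
    (peat, modern).
    """
    problems = {}
    for model in models:
        names = ("peat", "modern", "atmosphere") if model == "equilibration" else (
            "peat", "modern",
        )
        missing = [n for n in names if n not in end_members]
        if missing:
            raise ValueError(f"{model} model requires end members {missing}")
        problems[model] = MixingProblem(
            model=model,
            sources=tuple(end_members[n] for n in names),
            mixture=mixture,
        )
    return problems


def analyze_dataset(
    records: Sequence[PoolMeasurement],
    n_iter: int = 100_000,
    seed: int | np.random.SeedSequence | None = None,
    models: Sequence[str] = _MODEL_ORDER,
    source_pools: Mapping[str, str] = DEFAULT_SOURCE_POOLS,
    mixture_pool: str = "DIC",
    site: str | None = None,
    combine_mode: str = "pooled_variance",
    consistency_k: float = 1.0,
) -> dict:
    """Full inference on one measurement table.

    Builds end members and the mixture from empirical per-pool summaries
    (mean and sample s.d. across replicates), then delegates to
    :func:`run_models`.
    """
    summaries = summarize_pools(records)
    if site is None:
        sites = {s.site for s in summaries.values()}
        if len(sites) != 1:
            raise ValueError(
                f"table contains multiple sites {sorted(sites)}; pass site="
            )
        site = sites.pop()

    def _lookup(pool: str) -> PoolSummary:
        key = (site, pool)
        if key not in summaries:
            raise ValueError(f"no measurements for site={site!r} pool={pool!r}")
        return summaries[key]

    end_members = {
        name: _summary_to_end_member(name, _lookup(pool))
        for name, pool in source_pools.items()
    }
    mix = _lookup(mixture_pool)
    if mix.d13c_sd is None or mix.f14c_sd is None:
        raise ValueError(
            f"mixture pool ({site}, {mixture_pool}) has a single replicate; "
            f"cannot quantify its spread"
        )
    mixture = MixtureObs(
        d13c_mean=mix.d13c_mean,
        d13c_sd=mix.d13c_sd,
        f14c_mean=mix.f14c_mean,
        f14c_sd=mix.f14c_sd,
        label=f"{site}:{mixture_pool}",
    )
    problems = build_problems(end_members, mixture, models)
    return run_models(
        problems,
        n_iter=n_iter,
        seed=seed,
        combine_mode=combine_mode,
        consistency_k=consistency_k,
    )


# ---------------------------------------------------------------------------
# Config-driven driver


def _block_to_tracers(block: Mapping, what: str) -> tuple[float, float, float, float]:
    for key in ("d13c", "f14c"):
        if key not in block:
            raise ValueError(f"config {what}: missing {key!r} [mean, sd] pair")
        pair = block[key]
        if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
            raise ValueError(
                f"config {what}: {key} must be a [mean, sd] pair, got {pair!r}"
            )
    return (
        float(block["d13c"][0]),
        float(block["d13c"][1]),
        float(block["f14c"][0]),
        float(block["f14c"][1]),
    )


def _resolve_block(
    name: str,
    block: Mapping,
    summaries: dict[tuple[str, str], PoolSummary] | None,
) -> EndMember:
    if "site" in block or "pool" in block:
        if summaries is None:
            raise ValueError(
                f"config end_members.{name}: table-driven but no 'table' given"
            )
        key = (str(block["site"]), str(block["pool"]))
        if key not in summaries:
            raise ValueError(
                f"config end_members.{name}: no measurements for {key}"
            )
        return _summary_to_end_member(name, summaries[key])
    d13c_m, d13c_s, f14c_m, f14c_s = _block_to_tracers(block, f"end_members.{name}")
    return EndMember(
        name=name, d13c_mean=d13c_m, d13c_sd=d13c_s,
        f14c_mean=f14c_m, f14c_sd=f14c_s,
    )


def run_full_analysis(config: Mapping, samples_out: str | Path | None = None) -> dict:
    """Run the configured pipeline: mixing model(s) -> consistency ->
    inverse-variance combination -> flux upscaling.

    Config keys: ``end_members`` (name -> {d13c: [m, s], f14c: [m, s]} or
    {site, pool} with ``table``), ``mixture`` (same forms), ``model``
    (equilibration | outgassing | both), ``n_iter``, ``seed``, optional
    ``table`` (measurement CSV path), optional ``flux``
    ({areal_flux: scalar or [lo, hi], area_km2, fraction?}), optional
    ``combine_mode`` and ``consistency_k``.

    Returns a JSON-serialisable report; deterministic given the seed (no
    timestamps).
    """
    model_choice = config.get("model", "both")
    if model_choice == "both":
        models: tuple[str, ...] = _MODEL_ORDER
    elif model_choice in _MODEL_ORDER:
        models = (model_choice,)
    else:
        raise ValueError(
            f"config model must be 'equilibration', 'outgassing' or 'both', "
            f"got {model_choice!r}"
        )
    n_iter = int(config.get("n_iter", 100_000))
    seed = config.get("seed")
    seed = None if seed is None else int(seed)

    summaries = None
    provenance: dict = {"model": model_choice, "n_iter": n_iter, "seed": seed}
    if "table" in config and config["table"]:
        records = read_measurement_table(config["table"])
        summaries = summarize_pools(records)
        provenance["table"] = str(config["table"])

    if "end_members" not in config or "mixture" not in config:
        raise ValueError("config requires 'end_members' and 'mixture' blocks")
    end_members = {
        name: _resolve_block(name, block, summaries)
        for name, block in config["end_members"].items()
    }
    mix_block = config["mixture"]
    if "site" in mix_block or "pool" in mix_block:
        if summaries is None:
            raise ValueError("config mixture: table-driven but no 'table' given")
        key = (str(mix_block["site"]), str(mix_block["pool"]))
        if key not in summaries:
            raise ValueError(f"config mixture: no measurements for {key}")
        s = summaries[key]
        if s.d13c_sd is None or s.f14c_sd is None:
            raise ValueError(f"config mixture: single replicate at {key}")
        mixture = MixtureObs(
            d13c_mean=s.d13c_mean, d13c_sd=s.d13c_sd,
            f14c_mean=s.f14c_mean, f14c_sd=s.f14c_sd,
            label=f"{key[0]}:{key[1]}",
        )
    else:
        d13c_m, d13c_s, f14c_m, f14c_s = _block_to_tracers(mix_block, "mixture")
        mixture = MixtureObs(
            d13c_mean=d13c_m, d13c_sd=d13c_s,
            f14c_mean=f14c_m, f14c_sd=f14c_s,
            label=str(mix_block.get("label", "mixture")),
        )

    provenance["end_members"] = {
        n: {
            "d13c": [em.d13c_mean, em.d13c_sd],
            "f14c": [em.f14c_mean, em.f14c_sd],
        }
        for n, em in end_members.items()
    }
    provenance["mixture"] = {
        "label": mixture.label,
        "d13c": [mixture.d13c_mean, mixture.d13c_sd],
        "f14c": [mixture.f14c_mean, mixture.f14c_sd],
    }

    problems = build_problems(end_members, mixture, models)
    try:
        result = run_models(
            problems,
            n_iter=n_iter,
            seed=seed,
            combine_mode=config.get("combine_mode", "pooled_variance"),
            consistency_k=float(config.get("consistency_k", 1.0)),
        )
    except ZeroAcceptanceError as exc:
        raise ZeroAcceptanceError(f"mixing stage: {exc}") from exc

    if samples_out is not None:
        frames = []
        for model, post in result["posteriors"].items():
            frame = pd.DataFrame(post.samples, columns=list(post.source_names))
            frame.insert(0, "model", model)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(samples_out, index=False)

    report: dict = {
        "seed": seed,
        "models": {m: p.as_dict() for m, p in result["posteriors"].items()},
        "provenance": provenance,
    }
    if "combined" in result:
        report["consistency"] = result["consistency"]
        report["combined"] = result["combined"].as_dict()

    if "flux" in config and config["flux"]:
        fb = config["flux"]
        if "fraction" in fb and fb["fraction"] is not None:
            fraction = float(fb["fraction"])
            frac_src = "config override"
        elif "combined" in result:
            fraction = result["combined"].mean
            frac_src = "combined peat fraction"
        else:
            (only,) = result["posteriors"].values()
            fraction = only.mean("peat")
            frac_src = f"{only.model} peat fraction"
        flux_values = fb["areal_flux"]
        if not isinstance(flux_values, (list, tuple)):
            flux_values = [flux_values]
        area = float(fb["area_km2"])
        try:
            estimates = [
                annual_carbon_mass(float(f), area, fraction) for f in flux_values
            ]
        except ValueError as exc:
            raise ValueError(f"flux stage: {exc}") from exc
        report["flux"] = {
            "fraction_source": frac_src,
            "estimates": [e.as_dict() for e in estimates],
            "annual_mass_gg_c_range": [
                min(e.annual_mass_gg for e in estimates),
                max(e.annual_mass_gg for e in estimates),
            ],
        }
    return report
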