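"""End-to-end orchestration: events -> class proportions -> (tb, cb).

For every sample in a sample sheet the pipeline locates the female
internal-standard peak, screens it against the CV quality cutoff,
decomposes the male event region into GS-class proportions by finite
mixture modelling, and then per clone averages the replicate frequency
vectors, grid-fits the segregation parameters, tabulates O/E ratios
against the unbiased binomial expectation, and runs replicated G-tests
on the reconstructed first-class counts.  All outputs are plain text
(TSV/JSON) plus a run log; a second run with the same config reproduces
every number.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as iio
from .fitting import grid_fit
from .mixture import (
    CV_EXCLUSION_PERCENT,
    FluorescenceSample,
    assign_components_to_classes,
    fit_finite_mixture,
    qc_cv,
    renormalize_classes,
)
from .segmodel import ClassDistribution, unbiased_distribution, oe_ratios
from .stats import g_test, reconstruct_counts, repeated_g_test
from .synthetic_data import class_positions

__all__ = ["RunConfig", "run_pipeline", "estimate_female_peak",
           "decompose_sample", "PipelineResult"]

log = logging.getLogger("iseseg")


@dataclass(frozen=True)
class RunConfig:
    sample_sheet: Path
    karyotype_file: Path
    out_dir: Path
    grid_step: float = 0.05
    g_min: int = 3
    g_max: int = 8
    family: str = "skew_normal"
    tol: float = 1e-5
    max_iter: int = 1000
    cv_cutoff: float = CV_EXCLUSION_PERCENT
    match_window: float = 0.05
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.cv_cutoff <= 0:
            raise ValueError("cv_cutoff must be positive")


@dataclass
class PipelineResult:
    class_tables: dict
    qc: pd.DataFrame
    frequencies: dict
    fits: dict
    oe: pd.DataFrame
    gtests: dict
    excluded: list


def estimate_female_peak(events: np.ndarray) -> float:
    """Locate the female internal-standard peak in an event vector.

    The female diploid peak is the major mode in the upper quarter of
    the fluorescence range (male haploid classes sit at <= ~70% of it).
    A coarse histogram finds the densest upper bin; the refined position
    is the median of events within 5% of it.
    """
    e = np.asarray(events, dtype=float)
    hist, edges = np.histogram(e, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    upper = centers > 0.75 * e.max()
    if not upper.any():
        raise ValueError("cannot locate a female peak: no events in upper range")
    coarse = centers[upper][np.argmax(hist[upper])]
    near = e[np.abs(e - coarse) <= 0.05 * coarse]
    return float(np.median(near)) if near.size else float(coarse)


def decompose_sample(
    sample: FluorescenceSample,
    karyotype,
    config: Optional[RunConfig] = None,
    g_min: int = 3,
    g_max: int = 8,
    family: str = "skew_normal",
    tol: float = 1e-5,
    max_iter: int = 1000,
    match_window: float = 0.05,
    seed: int = 0,
):
    """Class proportions of one sample: mixture fit + class assignment.

    The female peak region is excluded from the mixture fit (it is the
    scaling standard, not a male class): only events below the midpoint
    between the largest male class position and the female peak enter
    the EM.  Returns (estimates, fit, female_peak).
    """
    if config is not None:
        g_min, g_max = config.g_min, config.g_max
        family, tol = config.family, config.tol
        max_iter, match_window = config.max_iter, config.match_window
        seed = config.seed
    female_peak = sample.female_peak_position
    if female_peak is None:
        female_peak = estimate_female_peak(sample.events)
    positions = class_positions(karyotype, reference=female_peak)
    cutoff = 0.5 * (positions[-1] + female_peak)
    male_events = sample.events[sample.events < cutoff]
    male_sample = FluorescenceSample(
        events=male_events,
        clone_id=sample.clone_id,
        stage=sample.stage,
        female_peak_position=female_peak,
        n_individuals=sample.n_individuals,
    )
    fit = fit_finite_mixture(
        male_sample, g_min=g_min, g_max=g_max, family=family,
        tol=tol, max_iter=max_iter, seed=seed,
    )
    raw = assign_components_to_classes(fit, positions, window=match_window)
    estimates = renormalize_classes(raw)
    return estimates, fit, female_peak


def _frequency_vector(estimates, n_ise: int) -> ClassDistribution:
    freqs = np.zeros(n_ise + 1)
    for e in estimates:
        freqs[e.class_k] = e.proportion
    return ClassDistribution(n_ise=n_ise, freqs=freqs / freqs.sum())


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis described in the module docstring."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "classes").mkdir(exist_ok=True)

    logging.basicConfig(
        level=logging.INFO if config.verbosity else logging.WARNING
    )
    logfile = out / "run.log"
    handler = logging.FileHandler(logfile, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> PipelineResult:
    import iseseg

    log.info("iseseg %s; seed=%d", getattr(iseseg, "__version__", "?"), config.seed)
    sheet = iio.read_sample_sheet(config.sample_sheet)
    karyotypes = iio.read_karyotypes(config.karyotype_file)
    base = Path(config.sample_sheet).parent

    qc_rows = []
    excluded = []
    class_tables: dict = {}
    per_clone_freqs: dict = {}
    per_clone_counts: dict = {}

    for idx, row in sheet.iterrows():
        sample_id = f"{row.clone_id}_{row.stage}_{idx}"
        if row.clone_id not in karyotypes:
            raise KeyError(
                f"sample {sample_id}: no karyotype for clone {row.clone_id!r} "
                f"in {config.karyotype_file}"
            )
        kar = karyotypes[row.clone_id]
        path = Path(row.file)
        if not path.is_absolute():
            path = base / path
        events = iio.read_events_csv(path)
        sample = FluorescenceSample(
            events=events,
            clone_id=str(row.clone_id),
            stage=str(row.stage),
            female_peak_position=(
                float(row.female_peak) if "female_peak" in sheet.columns
                and not pd.isna(row.get("female_peak")) else None
            ),
            n_individuals=int(row.n_males),
        )
        female_peak = sample.female_peak_position or estimate_female_peak(events)
        cv = qc_cv(sample, female_peak)
        is_excluded = cv > config.cv_cutoff
        qc_rows.append(
            {
                "sample_id": sample_id,
                "clone_id": row.clone_id,
                "stage": row.stage,
                "female_peak": female_peak,
                "cv_percent": cv,
                "excluded": is_excluded,
            }
        )
        if is_excluded:
            excluded.append(sample_id)
            log.info("sample %s excluded: female-peak CV %.2f%% > %.2f%%",
                     sample_id, cv, config.cv_cutoff)
            continue

        estimates, fit, _ = decompose_sample(sample, kar, config=config)
        class_tables[sample_id] = estimates
        iio.write_class_table(out / "classes" / f"{sample_id}.tsv", estimates)
        dist = _frequency_vector(estimates, kar.n_ise)
        per_clone_freqs.setdefault(row.clone_id, []).append(dist)
        per_clone_counts.setdefault(row.clone_id, []).append(
            (sample_id, str(row.stage), int(row.n_males), dist)
        )
        log.info("sample %s: g=%d bic=%.1f freqs=%s",
                 sample_id, fit.g, fit.bic, np.round(dist.freqs, 4))

    qc = pd.DataFrame(qc_rows)
    qc.to_csv(out / "qc.tsv", sep="\t", index=False)

    fits: dict = {}
    oe_rows = []
    gtests: dict = {}
    for clone_id, dists in per_clone_freqs.items():
        kar = karyotypes[clone_id]
        # mean of replicate frequency vectors, renormalised
        mean_f = np.mean([d.freqs for d in dists], axis=0)
        mean_dist = ClassDistribution(kar.n_ise, mean_f / mean_f.sum())
        fit = grid_fit(mean_dist, grid_step=config.grid_step)
        fits[clone_id] = fit
        iio.write_fit_result(
            out / f"fit_{clone_id}.json", fit, out / f"surface_{clone_id}.tsv"
        )
        expected = unbiased_distribution(kar.n_ise)
        table = oe_ratios(mean_dist, expected)
        for k in range(kar.n_ise + 1):
            oe_rows.append(
                {
                    "clone_id": clone_id,
                    "class_k": k,
                    "observed": table.observed[k],
                    "expected": table.expected[k],
                    "oe_ratio": table.ratio[k],
                }
            )
        gtests[clone_id] = _clone_gtests(
            per_clone_counts[clone_id], expected.freqs[0]
        )

    oe = pd.DataFrame(
        oe_rows, columns=["clone_id", "class_k", "observed", "expected", "oe_ratio"]
    )
    oe.to_csv(out / "oe.tsv", sep="\t", index=False)
    with open(out / "gtests.json", "w") as fh:
        json.dump(gtests, fh, indent=2)
    summary = {
        clone: {
            "best_tb": f.best_tb,
            "best_cb": None if math.isnan(f.best_cb) else f.best_cb,
            "best_rmse": f.best_rmse,
        }
        for clone, f in fits.items()
    }
    with open(out / "fits.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    log.info("fits: %s", summary)
    return PipelineResult(
        class_tables=class_tables,
        qc=qc,
        frequencies=per_clone_freqs,
        fits=fits,
        oe=oe,
        gtests=gtests,
        excluded=excluded,
    )


def _clone_gtests(samples, p_first: float) -> dict:
    """Replicated G-tests on first-GS-class counts across a clone's samples.

    Each sample's integer counts are reconstructed from its male number
    and the fitted proportion of the ISE-free class; the expectation is
    the unbiased probability of that class (0.5 for a single-ISE clone).
    """
    reps = []
    for sample_id, stage, n_males, dist in samples:
        p0 = float(dist.freqs[0])
        reps.append(
            reconstruct_counts(
                n_males, [p0, 1.0 - p0], stage=stage, replicate_id=sample_id
            )
        )
    probs = [p_first, 1.0 - p_first]
    if len(reps) >= 2:
        total, pooled, het = repeated_g_test(reps, probs)
        results = {"total": total, "pooled": pooled, "heterogeneity": het}
    else:
        results = {"pooled": g_test(reps[0], probs)}
    return {
        kind: {"G": r.G, "df": r.df, "p": r.p} for kind, r in results.items()
    }
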