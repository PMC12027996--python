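"""End-to-end orchestration: generation -> detection -> indicators ->
statistics -> ranges -> merge -> classification -> ROC.

Also houses the published reference range table (the per-paradigm
normalized Mean +- SD ranges for the significant indicators) shipped as a
TSV fixture, its internal-consistency check, and the "tables-only" mode
that feeds those printed ranges through the cross-paradigm merge stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import GazeEventDetector
from .indicators import (INDICATOR_NAMES, aggregate_repetitions,
                         records_to_frame, remove_outliers, summarize_trial,
                         write_trial_table)
from .ranges import (Interval, MergedRange, RangeDiscriminator, StateRange,
                     ZScorePool, merge_across_paradigms, range_report,
                     remove_overlap, round3, state_range, zscore)
from .roc import LogisticRivalryScorer, RocResult, kfold_roc, write_roc
from .stats import (DEFAULT_BONFERRONI_M, StatTestResult, interocular_screen,
                    two_group_screen, write_test_table)
from .synth import GROUPS, PARADIGMS, GeneratorParams, iter_cohort

log = logging.getLogger("gazestate")

#: per-paradigm logistic indicator subsets (blink duration excluded in the
#: static paradigm, SD amplitude excluded in the hopping paradigm)
DEFAULT_ROC_INDICATORS: dict[str, tuple[str, ...]] = {
    "gaze_stability": ("avg_saccade_amplitude", "median_saccade_amplitude",
                       "sd_saccade_amplitude"),
    "straight_curve": ("avg_saccade_amplitude", "median_saccade_amplitude",
                       "sac_avg_velocity", "sac_peak_velocity"),
    "smooth_pursuit": ("avg_saccade_amplitude", "median_saccade_amplitude",
                       "sd_saccade_amplitude"),
}


@dataclass(frozen=True)
class RunConfig:
    """Flat, human-editable pipeline configuration."""

    seed: int = 0
    n_subjects: int = 18
    paradigms: tuple[str, ...] = PARADIGMS
    sampling_rate: float = 500.0
    trial_duration: float | None = None     # None -> paradigm defaults
    effect_scale: float = 1.0               # 0 -> null world
    alpha: float = 0.05
    bonferroni_m: int = DEFAULT_BONFERRONI_M
    roc_mode: str = "resubstitution"        # or "kfold"
    roc_folds: int = 5
    detector: Mapping[str, float] = field(default_factory=dict)
    generator: Mapping[str, float] = field(default_factory=dict)
    outdir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "paradigms" in raw:
            raw["paradigms"] = tuple(raw["paradigms"])
        return cls(**raw)

    def generator_params(self) -> GeneratorParams:
        params = GeneratorParams(sampling_rate=self.sampling_rate,
                                 trial_duration=self.trial_duration,
                                 **dict(self.generator))
        if self.effect_scale != 1.0:
            params = replace(
                params,
                amplitude_effect={p: e * self.effect_scale
                                  for p, e in params.amplitude_effect.items()},
                blink_effect={p: e * self.effect_scale
                              for p, e in params.blink_effect.items()})
        return params

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    trials: pd.DataFrame
    units: pd.DataFrame
    interocular: list[StatTestResult]
    screen: list[StatTestResult]
    pools: dict[tuple[str, str], ZScorePool]
    paradigm_ranges: dict[tuple[str, str], dict[str, StateRange]]
    trimmed: dict[tuple[str, str], dict[str, Interval]]
    merged: dict[tuple[str, str], MergedRange]
    classification: pd.DataFrame
    roc: dict[str, RocResult]
    n_outliers_removed: int


def cohort_unit_table(n_subjects: int, params: GeneratorParams,
                      master_seed: int,
                      paradigms: Sequence[str] = PARADIGMS,
                      detector: GazeEventDetector | None = None,
                      use_ground_truth: bool = False,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort and reduce it to trial and unit tables.

    ``use_ground_truth=True`` bypasses event detection and summarises the
    generator's true event lists (fast oracle path for calibration tests).
    """
    detector = detector or GazeEventDetector()
    records = []
    for trial in iter_cohort(n_subjects, params, master_seed,
                             paradigms=paradigms):
        if use_ground_truth:
            events = {"left": trial.truth.events,
                      "right": trial.truth.events}
        else:
            events = detector.detect(trial.stream)
        records.append(summarize_trial(events, trial.stream, trial.meta,
                                       detector.geometry))
    trials = records_to_frame(records)
    units = aggregate_repetitions(trials)
    return trials, units


def reject_outliers(units: pd.DataFrame,
                    indicators: Sequence[str] = INDICATOR_NAMES,
                    ) -> tuple[pd.DataFrame, int]:
    """Blank outlying unit values per paradigm x state x indicator.

    Applies the union box-plot / 3-sigma rule within each pool; removed
    values become missing (listwise exclusion downstream).
    """
    units = units.copy()
    removed = 0
    for (_, _), idx in units.groupby(["paradigm", "state"]).groups.items():
        for name in indicators:
            col = units.loc[idx, name].dropna()
            if len(col) < 4:
                continue
            res = remove_outliers(col.to_numpy())
            if len(res.removed_indices):
                bad = col.index[res.removed_indices]
                units.loc[bad, name] = np.nan
                removed += len(bad)
    return units, removed


def build_ranges(units: pd.DataFrame,
                 indicators: Sequence[str] = INDICATOR_NAMES):
    """Z-score pools, per-state ranges and trimmed intervals per
    paradigm x indicator."""
    pools: dict[tuple[str, str], ZScorePool] = {}
    ranges: dict[tuple[str, str], dict[str, StateRange]] = {}
    trimmed: dict[tuple[str, str], dict[str, Interval]] = {}
    for paradigm, block in units.groupby("paradigm"):
        for name in indicators:
            vals = block[name]
            ok = vals.notna()
            states = block["state"][ok]
            if (states == "fusion").sum() < 2 or \
                    (states == "rivalry").sum() < 2:
                continue
            key = (paradigm, name)
            pool = ZScorePool.fit(vals[ok], paradigm, name,
                                  int((states == "fusion").sum()),
                                  int((states == "rivalry").sum()))
            z = zscore(vals[ok], pool)
            fus = state_range(z[(states == "fusion").to_numpy()], "fusion")
            riv = state_range(z[(states == "rivalry").to_numpy()], "rivalry")
            res = remove_overlap(fus.interval, riv.interval)
            pools[key] = pool
            ranges[key] = {"fusion": fus, "rivalry": riv}
            trimmed[key] = {"fusion": res.fusion, "rivalry": res.rivalry,
                            "abstain": res.abstain}
    return pools, ranges, trimmed


def merge_ranges(ranges, trimmed, indicators: Sequence[str],
                 ) -> dict[tuple[str, str], MergedRange]:
    """Cross-paradigm merge of the trimmed intervals per indicator."""
    merged: dict[tuple[str, str], MergedRange] = {}
    for name in indicators:
        per_par = {p: rr for (p, ind), rr in ranges.items() if ind == name}
        if len(per_par) < 2:
            continue
        directions = {p: rr["fusion"].mean - rr["rivalry"].mean
                      for p, rr in per_par.items()}
        for state in ("fusion", "rivalry"):
            ivs = {p: trimmed[(p, name)][state] for p in per_par
                   if not trimmed[(p, name)][state].is_empty}
            if len(ivs) < 2:
                continue
            try:
                merged[(name, state)] = merge_across_paradigms(
                    ivs, state, directions, indicator=name)
            except ValueError:
                log.warning("merge failed for %s/%s", name, state)
    return merged


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on a synthetic cohort; write reports if configured.

    Deterministic given ``config.seed``; every output file carries the
    configuration hash so identical configs rewrite byte-identically.
    """
    params = config.generator_params()
    detector = GazeEventDetector(**dict(config.detector))
    log.info("stage=simulate+detect subjects=%d paradigms=%s",
             config.n_subjects, ",".join(config.paradigms))
    trials, units = cohort_unit_table(config.n_subjects, params, config.seed,
                                      config.paradigms, detector)
    log.info("stage=indicators trials=%d units=%d", len(trials), len(units))
    units, n_removed = reject_outliers(units)
    log.info("stage=outliers removed=%d", n_removed)
    inter = interocular_screen(trials, config.alpha, config.bonferroni_m)
    screen = two_group_screen(units, config.alpha, config.bonferroni_m)
    n_sig = sum(r.significant for r in screen)
    log.info("stage=stats interocular=%d screen=%d significant=%d",
             len(inter), len(screen), n_sig)
    pools, ranges, trimmed = build_ranges(units)
    # merge indicators that screened significant in at least two paradigms
    sig_count: dict[str, int] = {}
    for r in screen:
        if r.significant:
            name = r.indicator.split(":", 1)[1]
            sig_count[name] = sig_count.get(name, 0) + 1
    merge_names = [n for n, c in sig_count.items() if c >= 2]
    merged = merge_ranges(ranges, trimmed, merge_names)
    log.info("stage=ranges pools=%d merged=%d", len(pools), len(merged))

    classification = classify_units(units, pools, merged)
    roc_results = paradigm_rocs(units, config)
    log.info("stage=roc paradigms=%d", len(roc_results))

    result = PipelineResult(config, trials, units, inter, screen, pools,
                            ranges, trimmed, merged, classification,
                            roc_results, n_removed)
    if config.outdir:
        write_report_bundle(result, Path(config.outdir))
    return result


def classify_units(units: pd.DataFrame, pools, merged,
                   indicator: str = "avg_saccade_amplitude") -> pd.DataFrame:
    """Per-unit state calls from the merged ranges of one indicator.

    Only units from paradigms included in both state intervals are
    classified; the merged range does not apply outside its own paradigm
    set.
    """
    key_f, key_r = (indicator, "fusion"), (indicator, "rivalry")
    if key_f not in merged or key_r not in merged:
        return pd.DataFrame(columns=["subject_id", "paradigm", "group",
                                     "state", "z", "call"])
    mf, mr = merged[key_f], merged[key_r]
    applicable = set(mf.included_paradigms) & set(mr.included_paradigms)
    disc = RangeDiscriminator.from_intervals(mf.interval, mr.interval)
    rows = []
    for _, row in units.iterrows():
        if row["paradigm"] not in applicable or \
                not np.isfinite(row[indicator]):
            continue
        pool = pools[(row["paradigm"], indicator)]
        z = float(zscore(row[indicator], pool))
        rows.append({"subject_id": row["subject_id"],
                     "paradigm": row["paradigm"], "group": row["group"],
                     "state": row["state"], "z": z,
                     "call": disc.predict(np.array([z]))[0]})
    return pd.DataFrame(rows)


def paradigm_rocs(units: pd.DataFrame, config: RunConfig,
                  ) -> dict[str, RocResult]:
    """Per-paradigm logistic ROC over the configured indicator subsets.

    Indicators are z-scored within paradigm before the fit; units with any
    missing selected indicator are dropped listwise.
    """
    out: dict[str, RocResult] = {}
    for paradigm, block in units.groupby("paradigm"):
        names = list(DEFAULT_ROC_INDICATORS.get(paradigm, INDICATOR_NAMES))
        data = block[names + ["state"]].dropna()
        y = (data["state"] == "rivalry").astype(int).to_numpy()
        if min(y.sum(), len(y) - y.sum()) < 2:
            continue
        X = data[names].to_numpy()
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        if config.roc_mode == "kfold":
            out[paradigm] = kfold_roc(X, y, config.roc_folds, config.seed)
        else:
            est = LogisticRivalryScorer().fit(X, y)
            out[paradigm] = est.evaluate(X, y)
    return out


# ---------------------------------------------------------------------------
# Report bundle

def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def write_report_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash()
    _write_tsv(result.trials, outdir / "trials.tsv", h)
    _write_tsv(result.units, outdir / "units.tsv", h)
    write_test_table(result.interocular, outdir / "interocular.tsv")
    write_test_table(result.screen, outdir / "screen.tsv")
    rows = []
    for (paradigm, name), rr in result.paradigm_ranges.items():
        for state in ("fusion", "rivalry"):
            iv = result.trimmed[(paradigm, name)][state]
            rows.append({"paradigm": paradigm, "indicator": name,
                         "state": state, "mean": iv.midpoint,
                         "sd": iv.half_width, "lower": iv.lower,
                         "upper": iv.upper, "included_paradigms": paradigm})
    _write_tsv(range_report(rows), outdir / "ranges_by_paradigm.tsv", h)
    rows = []
    for (name, state), m in result.merged.items():
        rows.append({"paradigm": "merged", "indicator": name, "state": state,
                     "mean": m.midpoint, "sd": m.half_width,
                     "lower": m.interval.lower, "upper": m.interval.upper,
                     "included_paradigms": "+".join(m.included_paradigms)})
    _write_tsv(range_report(rows), outdir / "ranges_merged.tsv", h)
    _write_tsv(result.classification, outdir / "classification.tsv", h)
    for paradigm, roc in result.roc.items():
        write_roc(roc, outdir / f"roc_{paradigm}.tsv",
                  outdir / f"roc_{paradigm}.json")
    provenance = {"config": asdict(result.config), "config_hash": h,
                  "package_version": __version__,
                  "n_outliers_removed": result.n_outliers_removed,
                  "auc": {p: r.auc for p, r in result.roc.items()}}
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True, default=str))


# ---------------------------------------------------------------------------
# Published reference ranges (tables-only mode)

MERGEABLE_INDICATORS = ("avg_saccade_amplitude", "median_saccade_amplitude",
                        "sd_saccade_amplitude")


@dataclass
class PrintedRange:
    mean: float
    sd: float
    lower: float
    upper: float

    @property
    def interval(self) -> Interval:
        return Interval(self.lower, self.upper)


def load_table1_fixture(path: str | Path | None = None,
                        ) -> dict[tuple[str, str], dict[str, PrintedRange]]:
    """Load the transcribed per-paradigm reference ranges.

    Returns ``{(paradigm, indicator): {state: PrintedRange}}`` with 12
    indicator x paradigm rows, each holding a fusion and a rivalry range.
    Schema violations raise with the offending cell named.
    """
    if path is None:
        src = resources.files("gazestate").joinpath("data/table1.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"paradigm", "indicator", "state", "mean", "sd",
                "lower", "upper"}
    if set(df.columns) != required:
        raise ValueError(f"fixture schema mismatch: {sorted(df.columns)}")
    out: dict[tuple[str, str], dict[str, PrintedRange]] = {}
    for _, row in df.iterrows():
        cell = f"{row['paradigm']}/{row['indicator']}/{row['state']}"
        if row["state"] not in ("fusion", "rivalry"):
            raise ValueError(f"bad state in {cell}")
        for col in ("mean", "sd", "lower", "upper"):
            if not np.isfinite(row[col]):
                raise ValueError(f"non-numeric {col} in {cell}")
        if row["lower"] > row["upper"]:
            raise ValueError(f"inverted range in {cell}")
        out.setdefault((row["paradigm"], row["indicator"]), {})[
            row["state"]] = PrintedRange(row["mean"], row["sd"],
                                         row["lower"], row["upper"])
    for key, states in out.items():
        if set(states) != {"fusion", "rivalry"}:
            raise ValueError(f"missing state for {key}")
    return out


def check_table1(fixture) -> list[str]:
    """Endpoint-consistency check on the printed reference ranges.

    For each row and state, each printed endpoint must equal mean -+ sd to
    printed precision (within half a rounding unit, 0.0015), OR be an
    overlap-trimmed endpoint: strictly inside the raw Mean +- SD interval
    and coinciding with the adjacent endpoint of the other state.  Returns
    the list of flagged (inconsistent) cells.
    """
    flagged = []
    tol = 1.5e-3
    for (paradigm, indicator), states in sorted(fixture.items()):
        for state, pr in sorted(states.items()):
            other = states["rivalry" if state == "fusion" else "fusion"]
            raw_lo, raw_hi = pr.mean - pr.sd, pr.mean + pr.sd
            for name, printed, raw in (("lower", pr.lower, raw_lo),
                                       ("upper", pr.upper, raw_hi)):
                if abs(printed - raw) <= tol:
                    continue
                trimmed_ok = (raw_lo - tol <= printed <= raw_hi + tol) and (
                    abs(printed - other.lower) <= tol
                    or abs(printed - other.upper) <= tol)
                if not trimmed_ok:
                    flagged.append(f"{paradigm}/{indicator}/{state}/{name}")
    return flagged


def merge_table(fixture=None) -> pd.DataFrame:
    """Feed the printed per-paradigm ranges through the merge stage.

    Reproduces the cross-paradigm merged table for the indicators present
    in every paradigm: merged Range by interval intersection (dropping a
    direction-inverted paradigm when it empties the intersection) and
    merged Mean +- SD as midpoint +- half-width, to 3 decimals.
    """
    fixture = fixture if fixture is not None else load_table1_fixture()
    paradigms = sorted({p for p, _ in fixture})
    rows = []
    for name in MERGEABLE_INDICATORS:
        per_par = {p: fixture[(p, name)] for p in paradigms
                   if (p, name) in fixture}
        if len(per_par) < 2:
            continue
        directions = {p: st["fusion"].mean - st["rivalry"].mean
                      for p, st in per_par.items()}
        for state in ("fusion", "rivalry"):
            ivs = {p: st[state].interval for p, st in per_par.items()}
            m = merge_across_paradigms(ivs, state, directions, name)
            rows.append({"paradigm": "merged", "indicator": name,
                         "state": state, "mean": m.midpoint,
                         "sd": m.half_width, "lower": m.interval.lower,
                         "upper": m.interval.upper,
                         "included_paradigms":
                             "+".join(m.included_paradigms)})
    return range_report(rows)
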