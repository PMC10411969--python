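"""Full-analysis orchestration: simulate or load, screen, code, decide, decode.

``run_pipeline`` executes every stage of the shared-code analysis on one
population and writes machine-readable CSV tables plus a JSON run manifest.
Every stochastic stage consumes its own child generator spawned
deterministically from the master seed, so a fixed configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .action_coding import coding_flags
from .angle_analysis import angle_points, boundary_over_thresholds, threshold_labels
from .io import read_population_csv, sim_config_from_dict, write_ground_truth_csv, write_population_csv
from .mn_criteria import screen_population
from .permutation_null import null_distribution
from .population_decoding import binwise_subpopulations, population_accuracy
from .records import bin_population
from .segments import extract_segments
from .shared_code import (
    LABEL_NAMES,
    SHARED,
    classifier_accuracies,
    cross_task_labels_from_pvalues,
    same_discharge,
    same_preference,
)
from .synthetic import SimConfig, simulate_population
from .timebase import ACTION_PERIOD_BINS

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

METHODS = ("discharge", "preference", "lda")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the manifest names the stage."""


@dataclass
class PipelineConfig:
    """Analysis constants (defaults are the study conditions) and run setup."""

    out_dir: str = "mirrorcode_out"
    simulate: SimConfig | None = None
    input_path: str | None = None
    alpha: float = 0.05
    n_boot: int = 1000
    n_boot_null: int = 200
    n_perm: int = 250
    thresholds: tuple[float, ...] = tuple(float(t) for t in range(5, 16))
    label_threshold: float = 10.0
    seed: int = 0
    write_population: bool = False

    @classmethod
    def from_yaml_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = sim_config_from_dict(d["simulate"])
        if "thresholds" in d:
            d["thresholds"] = tuple(float(t) for t in d["thresholds"])
        return cls(**d)

    def __post_init__(self) -> None:
        if self.simulate is None and self.input_path is None:
            raise ValueError("config needs either a simulate spec or an input_path")


@dataclass
class _Manifest:
    stages: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def record(self, name: str, status: str, seconds: float, **info) -> None:
        self.stages.append({"stage": name, "status": status, "seconds": round(seconds, 3), **info})

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"version": self.version, "seed": self.seed, "counts": self.counts,
                 "stages": self.stages},
                fh, indent=2,
            )


def _bin_label(b0: int) -> int:
    """1-based grid bin number of an action-period index 0..11."""
    return int(ACTION_PERIOD_BINS[b0]) + 1


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write CSV tables and manifest.json to out_dir.

    Returns the manifest dict; raises PipelineError (after writing the
    manifest with the completed stages) if a stage fails.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    child = {name: np.random.default_rng(s) for name, s in zip(
        ("simulate", "accuracy", "preference", "null_discharge", "null_preference",
         "null_lda", "angle", "population"),
        ss.spawn(8),
    )}

    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            info = fn() or {}
        except Exception as exc:
            manifest.record(name, "failed", time.perf_counter() - t0, error=str(exc))
            manifest.write(out / "manifest.json")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, "ok", time.perf_counter() - t0, **info)

    # -- population -------------------------------------------------------
    def s_population():
        if config.simulate is not None:
            recs, truth = simulate_population(config.simulate, child["simulate"])
            state["recordings"] = recs
            if config.write_population:
                write_population_csv(recs, out / "population.csv")
                write_ground_truth_csv(truth, out / "ground_truth.csv")
        else:
            state["recordings"] = read_population_csv(config.input_path)
        return {"n_neurons": len(state["recordings"])}

    stage("population", s_population)

    def s_binning():
        state["binned"] = bin_population(state["recordings"])

    stage("binning", s_binning)

    def s_screening():
        kept, screens = screen_population(state["binned"], alpha=config.alpha)
        pd.DataFrame(
            [{"neuron_id": s.neuron_id, "motor": s.motor, "visual": s.visual,
              "mirror": s.mirror, "excluded": s.excluded or ""} for s in screens]
        ).to_csv(out / "screening.csv", index=False)
        if not kept:
            raise RuntimeError("no neuron passed the mirror-neuron screen")
        state["kept"] = kept
        return {"n_mirror": len(kept), "n_recorded": len(screens)}

    stage("screening", s_screening)

    def s_coding():
        coding = coding_flags(state["kept"], alpha=config.alpha)
        state["coding"] = coding
        n = coding.n_neurons
        rows = []
        for b in range(24):
            rows.append({
                "bin": b + 1,
                "n_exe_coding": int(coding.rej_exe[:, b].sum()),
                "n_obs_coding": int(coding.rej_obs[:, b].sum()),
                "n_neurons": n,
            })
        pd.DataFrame(rows).to_csv(out / "coding_bins.csv", index=False)
        n_all = n * 12
        summary = {
            "n_neurons": n,
            "n_action_period_bins": n_all,
            "n_obs_coding": int(coding.obs_coding().sum()),
            "n_exe_coding": int(coding.exe_coding().sum()),
            "n_both": int(coding.both_coding().sum()),
            "n_obs_only": int(coding.obs_only().sum()),
        }
        summary["pct_obs_coding"] = 100.0 * summary["n_obs_coding"] / n_all
        pd.DataFrame([summary]).to_csv(out / "coding_summary.csv", index=False)
        manifest.counts.update(summary)

    stage("coding", s_coding)

    def s_accuracy():
        acc: dict[int, dict] = {}
        for i, neuron in enumerate(state["kept"]):
            acc[i] = classifier_accuracies(
                neuron, bins=ACTION_PERIOD_BINS, n_boot=config.n_boot,
                rng=child["accuracy"],
            )
        state["acc"] = acc
        rows = [
            {"neuron_id": state["kept"][i].neuron_id, "bin": b + 1, "mode": mode,
             "mean_accuracy": d.mean, "p_vs_chance": d.p_vs_chance}
            for i, dd in acc.items() for (b, mode), d in dd.items()
        ]
        pd.DataFrame(rows).to_csv(out / "accuracy_single.csv", index=False)

    stage("single_neuron_accuracy", s_accuracy)

    def s_labels():
        kept, coding = state["kept"], state["coding"]
        n = len(kept)
        p_e2o = np.full((n, 12), np.nan)
        for i, dd in state["acc"].items():
            for j, b0 in enumerate(ACTION_PERIOD_BINS):
                p_e2o[i, j] = dd[(int(b0), "e2o")].p_vs_chance
        labels = {
            "discharge": same_discharge(kept, coding, alpha=config.alpha),
            "preference": same_preference(
                kept, coding, n_boot=config.n_boot, rng=child["preference"],
                alpha=config.alpha,
            ),
            "lda": cross_task_labels_from_pvalues(coding, p_e2o, alpha=config.alpha),
        }
        state["labels"] = labels
        frac_rows = []
        for method, lab in labels.items():
            _write_labels(out / f"labels_{method}.csv", kept, lab)
            n_all = lab.size
            n_shared = int((lab == SHARED).sum())
            frac_rows.append({
                "method": method,
                "n_shared_bins": n_shared,
                "n_examined_bins": int(coding.both_coding().sum()),
                "n_all_bins": n_all,
                "pct_shared_of_all": 100.0 * n_shared / n_all,
                "n_shared_neurons": int((lab == SHARED).any(axis=1).sum()),
                "n_neurons": n,
            })
        pd.DataFrame(frac_rows).to_csv(out / "shared_fractions.csv", index=False)

    stage("shared_labels", s_labels)

    def s_nulls():
        kept, coding = state["kept"], state["coding"]
        rows = []
        state["nulls"] = {}
        for method in METHODS:
            nd = null_distribution(
                kept, method, n_perm=config.n_perm, rng=child[f"null_{method}"],
                coding=coding, n_boot=config.n_boot_null, alpha=config.alpha,
            )
            state["nulls"][method] = nd
            lab = state["labels"][method]
            for which, observed in (
                ("bins", int((lab == SHARED).sum())),
                ("neurons", int((lab == SHARED).any(axis=1).sum())),
            ):
                lo, hi = nd.interval(which)
                rows.append({
                    "method": method, "statistic": f"shared_{which}",
                    "observed": observed, "null_mean": nd.mean(which),
                    "null_lo95": lo, "null_hi95": hi, "n_perm": config.n_perm,
                })
        pd.DataFrame(rows).to_csv(out / "null_intervals.csv", index=False)

    stage("permutation_null", s_nulls)

    def s_angle():
        kept = state["kept"]
        ids = list(range(len(kept)))
        e2o = np.array([[state["acc"][i][(int(b), "e2o")].mean for b in ACTION_PERIOD_BINS]
                        for i in ids])
        o2o = np.array([[state["acc"][i][(int(b), "o2o")].mean for b in ACTION_PERIOD_BINS]
                        for i in ids])
        points = angle_points(ids, e2o, o2o)
        state["points"] = points
        # keep only thresholds with a comfortable margin over the 30-point
        # fit floor, so bootstrap resamples rarely dip below it
        usable = [t for t in config.thresholds if points.above(t).sum() >= 45]
        dropped = [t for t in config.thresholds if t not in usable]
        if not usable:
            raise RuntimeError("no filtering threshold retains enough angle points")
        pd.DataFrame({
            "neuron_id": [kept[i].neuron_id for i in points.neuron],
            "ap_bin": points.bin_index + 1,
            "e2o_rel_pp": points.e2o_rel,
            "o2o_rel_pp": points.o2o_rel,
            "angle_deg": points.angle,
        }).to_csv(out / "angle_points.csv", index=False)
        res = boundary_over_thresholds(
            points, thresholds=np.asarray(usable),
            n_boot=config.n_boot, rng=child["angle"],
        )
        state["boundary"] = res
        rows = []
        for ti, f in enumerate(res.fits):
            rows.append({
                "threshold_pp": res.thresholds[ti], "n_points": f.n_points,
                "adj_r2": f.adj_r2, "peak_lower": f.peaks[0], "peak_upper": f.peaks[1],
                "boundary": f.boundary,
                "boundary_lo95": res.ci_boundary[ti, 0],
                "boundary_hi95": res.ci_boundary[ti, 1],
                "failure_rate": res.failure_rates[ti],
            })
        df = pd.DataFrame(rows)
        df.loc[len(df)] = {"threshold_pp": "average", "boundary": res.average_boundary}
        df.to_csv(out / "boundary.csv", index=False)
        lab = threshold_labels(
            points, boundary=res.average_boundary, threshold=config.label_threshold,
            n_neurons=len(kept), neuron_ids=ids,
        )
        state["labels"]["threshold"] = lab
        _write_labels(out / "labels_threshold.csv", kept, lab)
        return {"average_boundary_deg": res.average_boundary,
                "thresholds_dropped": dropped}

    stage("angle_analysis", s_angle)

    def s_segments():
        kept = state["kept"]
        rows = []
        for method in ("preference", "lda", "threshold"):
            lab = state["labels"][method]
            for i in range(lab.shape[0]):
                for seg in extract_segments(lab[i], neuron=i):
                    rows.append({
                        "method": method, "neuron_id": kept[seg.neuron].neuron_id,
                        "code_type": seg.code_type, "start": seg.start,
                        "duration": seg.duration,
                    })
        pd.DataFrame(rows, columns=["method", "neuron_id", "code_type", "start", "duration"]
                     ).to_csv(out / "segments.csv", index=False)

    stage("segments", s_segments)

    def s_population_decoding():
        kept = state["kept"]
        rng = child["population"]
        rows = []

        def run(subset_name, neurons, modes, bins):
            for b0 in bins:
                for mode in modes:
                    if not neurons:
                        rows.append({"subset": subset_name, "mode": mode,
                                     "bin": _bin_label(b0), "n_neurons": 0,
                                     "mean_accuracy": np.nan,
                                     "lo90": np.nan, "hi90": np.nan})
                        continue
                    pa = population_accuracy(
                        neurons, int(ACTION_PERIOD_BINS[b0]), mode,
                        n_boot=config.n_boot, rng=rng, subset=subset_name,
                    )
                    rows.append({"subset": subset_name, "mode": mode,
                                 "bin": _bin_label(b0), "n_neurons": pa.n_neurons,
                                 "mean_accuracy": pa.mean,
                                 "lo90": pa.ci[0], "hi90": pa.ci[1]})

        bins12 = list(range(12))
        run("all", kept, ("e2e", "o2o", "e2o", "o2e"), bins12)
        any_shared = binwise_subpopulations(state["labels"]["lda"], "any_shared")["neurons"]
        run("any_shared_lda", [kept[i] for i in any_shared], ("e2o", "o2o"), bins12)
        only_thr = binwise_subpopulations(
            state["labels"]["threshold"], "only_shared_threshold"
        )["neurons"]
        run("only_shared_threshold", [kept[i] for i in only_thr], ("e2o", "o2o"), bins12)
        for name, lab in (("per_bin_lda", state["labels"]["lda"]),
                          ("per_bin_threshold", state["labels"]["threshold"])):
            per_bin = binwise_subpopulations(lab, "per_bin_shared")["per_bin"]
            for b0 in bins12:
                run(name, [kept[i] for i in per_bin[b0]], ("e2o", "o2o"), [b0])
        pd.DataFrame(rows).to_csv(out / "population_accuracy.csv", index=False)
        return {"n_any_shared_lda": int(len(any_shared)),
                "n_only_shared_threshold": int(len(only_thr))}

    stage("population_decoding", s_population_decoding)

    manifest.write(out / "manifest.json")
    with open(out / "manifest.json") as fh:
        return json.load(fh)


def _write_labels(path: Path, kept, labels: np.ndarray) -> None:
    rows = [
        {"neuron_id": kept[i].neuron_id, "ap_bin": j + 1,
         "label": LABEL_NAMES[labels[i, j]]}
        for i in range(labels.shape[0]) for j in range(labels.shape[1])
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
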