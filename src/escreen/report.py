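"""Screen-level summaries, heatmap clustering, and pipeline orchestration.

``summarize_actives`` condenses an activity-call table (or the packaged
published-results fixture) into the headline numbers of a screen: actives
per endpoint, potency extremes, sub-micromolar and >10 µM counts, and the
active fraction of the library. ``hcluster`` provides the Euclidean/Ward
two-dimensional hierarchical clustering used to order heatmaps.
``run_pipeline`` chains simulate -> process -> call -> associate -> model
-> report into a reproducible artifact directory.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy

from . import assoc, doseresponse, icw, linmod, simulate
from .doseresponse import ENDPOINTS

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    pass


class PipelineError(RuntimeError):
    pass


def load_table1() -> pd.DataFrame:
    """Packaged fixture of published per-chemical AC50 values (µM).

    Columns chemical/endpoint/ac50_uM; endpoint labels follow the calling
    convention (cell_loss = increased cytotoxicity, cell_gain = increased
    cell number, diff_decrease / diff_increase for differentiation).
    """
    ref = importlib.resources.files("escreen.fixtures") / "table1_ac50.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


@dataclass(frozen=True)
class ScreenSummary:
    """Recomputable headline numbers of an activity-call table (AC50s in µM)."""

    endpoint_counts: dict
    endpoint_min: dict  # endpoint -> (chemical, ac50_uM)
    endpoint_max: dict
    n_active_chemicals: int
    library_size: int
    fraction_active: float
    n_ac50_values: int
    n_submicromolar: int
    n_above_10uM: int
    n_ushape_chemicals: int

    def to_dict(self) -> dict:
        return {
            "endpoint_counts": dict(self.endpoint_counts),
            "endpoint_min": {k: list(v) for k, v in self.endpoint_min.items()},
            "endpoint_max": {k: list(v) for k, v in self.endpoint_max.items()},
            "n_active_chemicals": self.n_active_chemicals,
            "library_size": self.library_size,
            "fraction_active": self.fraction_active,
            "n_ac50_values": self.n_ac50_values,
            "n_submicromolar": self.n_submicromolar,
            "n_above_10uM": self.n_above_10uM,
            "n_ushape_chemicals": self.n_ushape_chemicals,
        }

    def summary(self) -> str:
        lines = [
            "Screen activity summary",
            "=" * 55,
            f"chemicals with >= 1 AC50   {self.n_active_chemicals:>6d} "
            f"({100 * self.fraction_active:.1f}% of {self.library_size})",
            f"AC50 values calculated     {self.n_ac50_values:>6d}",
            f"  below 1 uM               {self.n_submicromolar:>6d}",
            f"  above 10 uM              {self.n_above_10uM:>6d}",
            f"nonmonotone (U-shape)      {self.n_ushape_chemicals:>6d}",
            "",
            f"{'endpoint':<16}{'actives':>8}{'min AC50 (uM)':>22}{'max AC50 (uM)':>22}",
            "-" * 68,
        ]
        for ep in ENDPOINTS:
            lo = self.endpoint_min.get(ep)
            hi = self.endpoint_max.get(ep)
            lines.append(
                f"{ep:<16}{self.endpoint_counts.get(ep, 0):>8d}"
                f"{(f'{lo[1]:g} ({lo[0]})' if lo else '-'):>22}"
                f"{(f'{hi[1]:g} ({hi[0]})' if hi else '-'):>22}"
            )
        return "\n".join(lines)


def summarize_actives(calls: pd.DataFrame, library_size: int | None = None) -> ScreenSummary:
    """Compute every summary field by counting over the call table.

    Accepts a full call table from ``call_screen`` (with ``active``/
    ``shape``) or a bare actives table like the packaged fixture
    (chemical/endpoint/ac50_uM, every row active).
    """
    calls = calls.copy()
    unknown = set(calls["endpoint"].unique()) - set(ENDPOINTS) - {"none", "missing"}
    if unknown:
        raise SchemaError(f"unknown endpoint labels {sorted(unknown)}")
    if "active" not in calls.columns:
        calls["active"] = True
    active = calls[calls["active"].astype(bool) & calls["ac50_uM"].notna()]

    counts, mins, maxs = {}, {}, {}
    for ep in ENDPOINTS:
        sub = active[active["endpoint"] == ep]
        counts[ep] = int(len(sub))
        if len(sub):
            lo = sub.loc[sub["ac50_uM"].idxmin()]
            hi = sub.loc[sub["ac50_uM"].idxmax()]
            mins[ep] = (str(lo["chemical"]), float(lo["ac50_uM"]))
            maxs[ep] = (str(hi["chemical"]), float(hi["ac50_uM"]))

    n_active = int(active["chemical"].nunique())
    if library_size is None:
        library_size = int(calls["chemical"].nunique())
    values = active["ac50_uM"].to_numpy(float)
    if "shape" in calls.columns:
        n_ushape = int(calls.loc[calls["shape"] == "ushape", "chemical"].nunique())
    else:
        n_ushape = 0
    return ScreenSummary(
        endpoint_counts=counts, endpoint_min=mins, endpoint_max=maxs,
        n_active_chemicals=n_active, library_size=library_size,
        fraction_active=n_active / library_size if library_size else 0.0,
        n_ac50_values=int(values.size),
        n_submicromolar=int(np.sum(values < 1.0)),
        n_above_10uM=int(np.sum(values > 10.0)),
        n_ushape_chemicals=n_ushape,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering (heatmap ordering)


@dataclass(frozen=True)
class ClusterResult:
    """Row/column leaf orders and Ward merge trees for heatmap layout."""

    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    metric: str = "euclidean"
    method: str = "ward"


def _ward_order(frame: pd.DataFrame):
    if len(frame) < 2:
        return list(frame.index), None
    linkage = hierarchy.linkage(frame.to_numpy(float), method="ward")
    order = hierarchy.leaves_list(linkage)
    return [frame.index[i] for i in order], linkage


def hcluster(matrix: pd.DataFrame) -> ClusterResult:
    """Two-dimensional agglomerative clustering, Euclidean metric, Ward linkage.

    Rows and columns are clustered independently. Inputs are first sorted
    by id so the result is invariant to the incoming row/column order (the
    canonical tie-break on equal merge costs).
    """
    if len(matrix) < 2:
        raise SchemaError("need >= 2 rows to cluster")
    matrix = matrix.sort_index().sort_index(axis=1)
    row_order, row_linkage = _ward_order(matrix)
    col_order, col_linkage = _ward_order(matrix.T)
    return ClusterResult(row_order, col_order, row_linkage, col_linkage)


def plot_heatmap(matrix: pd.DataFrame, cluster: ClusterResult | None = None, ax=None):
    """Optional thin heatmap rendering of a (clustered) activity matrix."""
    import matplotlib.pyplot as plt  # deferred; plotting is optional

    if cluster is None:
        cluster = hcluster(matrix)
    ordered = matrix.loc[cluster.row_order, cluster.col_order]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(3, 0.2 * len(ordered))))
    im = ax.imshow(ordered.to_numpy(float), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="-log10 AC50 (M)")
    return ax


# ---------------------------------------------------------------------------
# Pipeline


DEFAULT_CONFIG = {
    "seed": 1,
    "n_chemicals": 24,
    "n_triplicates": 0,
    "cv_intensity": 0.05,
    "background_mean": 500.0,
    "background_sd": 50.0,
    "alpha": 0.1,
    "k_folds": 5,
    "n_external_assays": 8,
    "linmod_output": "diff_decrease",
    "wells_csv": None,  # when set, skip simulation and process this file
    "outdir": "escreen_run",
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    merged = dict(DEFAULT_CONFIG)
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    merged.update(config)
    return merged


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config) -> dict:
    """Execute simulate -> process -> call -> associate -> model -> report.

    Returns {artifact name: path}. Every artifact except the run log is a
    deterministic function of the configuration (including its seed).
    """
    cfg = _load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log_lines = [
        f"python {platform.python_version()}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"config: {json.dumps({k: v for k, v in cfg.items()}, sort_keys=True)}",
    ]

    @_stage("simulate")
    def do_simulate():
        noise = simulate.NoiseModel(
            cv_intensity=cfg["cv_intensity"], background_mean=cfg["background_mean"],
            background_sd=cfg["background_sd"], seed=cfg["seed"],
        )
        wells, truth = simulate.generate_screen(
            cfg["n_chemicals"], noise=noise, n_triplicates=cfg["n_triplicates"],
        )
        wells.to_csv(outdir / "wells.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
        artifacts["wells"] = outdir / "wells.csv"
        artifacts["truth"] = outdir / "truth.csv"
        return wells, truth

    @_stage("process")
    def do_process(wells):
        responses = icw.process_screen(wells)
        icw.write_responses(responses, outdir / "responses.csv")
        artifacts["responses"] = outdir / "responses.csv"
        return responses

    @_stage("call")
    def do_call(responses):
        calls = doseresponse.call_screen(responses)
        doseresponse.write_calls(calls, outdir / "calls.csv")
        artifacts["calls"] = outdir / "calls.csv"
        return calls

    @_stage("associate")
    def do_associate(calls, truth):
        if truth is not None and cfg["n_external_assays"]:
            extra = simulate.generate_external_assays(
                truth, n_assays=cfg["n_external_assays"], seed=cfg["seed"] + 1,
            )
            extra = extra.reindex(sorted(set(calls["chemical"]))).fillna(
                assoc.INACTIVE_AC50_M
            )
        else:
            extra = None
        matrix = assoc.AssayMatrix.from_calls(calls, extra=extra)
        matrix.to_csv(outdir / "matrix.csv")
        artifacts["matrix"] = outdir / "matrix.csv"
        table = assoc.association_screen(matrix, alpha=cfg["alpha"])
        table.to_csv(outdir / "associations.csv", index=False)
        artifacts["associations"] = outdir / "associations.csv"
        return matrix

    @_stage("model")
    def do_model(matrix):
        out_col = cfg["linmod_output"]
        scores = matrix.scale_scores()
        y = matrix.dichotomize()[out_col].to_numpy()
        inputs = scores.drop(columns=[c for c in ENDPOINTS if c in scores.columns])
        k = min(cfg["k_folds"], int(y.sum()), int(len(y) - y.sum()))
        path = outdir / "linmod.json"

        def skip(reason):
            path.write_text(json.dumps(
                {"output": out_col, "fitted": False, "reason": reason},
                indent=2) + "\n")
            artifacts["linmod"] = path

        if k < 2 or inputs.shape[1] == 0:
            skip("output class too small for cross-validation")
            return None
        try:
            results = linmod.fit_linmod(inputs, y, k_folds=k, seed=cfg["seed"],
                                        output_name=out_col)
        except linmod.UndefinedAUCError as exc:
            skip(str(exc))
            return None
        results.to_json(path)
        artifacts["linmod"] = path
        preds = pd.DataFrame({
            "chemical": scores.index,
            "score": results.decision_scores(inputs),
            "predicted": results.predict(inputs).astype(int),
            "truth": y,
        })
        preds.to_csv(outdir / "predictions.csv", index=False)
        artifacts["predictions"] = outdir / "predictions.csv"
        return results

    @_stage("report")
    def do_report(calls):
        summary = summarize_actives(calls)
        (outdir / "summary.json").write_text(
            json.dumps(summary.to_dict(), indent=2, sort_keys=True) + "\n")
        artifacts["summary"] = outdir / "summary.json"
        return summary

    if cfg["wells_csv"] is not None:
        wells_path = Path(cfg["wells_csv"])
        if not wells_path.exists():
            raise PipelineError(f"stage 'simulate' failed: input path {wells_path} not found")
        wells, truth = pd.read_csv(wells_path), None
    else:
        wells, truth = do_simulate()
    responses = do_process(wells)
    calls = do_call(responses)
    matrix = do_associate(calls, truth)
    do_model(matrix)
    do_report(calls)

    import datetime

    log_lines.append(f"completed {datetime.datetime.now().isoformat()}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    artifacts["log"] = outdir / "run.log"
    return artifacts
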