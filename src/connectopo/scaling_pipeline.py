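"""Finite-size scaling fits, slope tests and end-to-end orchestration.

Two nonlinear least-squares forms cover the finite-size analyses:
``y = a + b x^c`` with ``x = 1/N`` (invariants versus inverse size) and
``y = A + B N^C`` (dimension versus size).  A simple zero-slope t-test on
(optionally log-transformed) series flags statistically significant size
dependence.  ``analyze_graph`` chains the whole pipeline — component
extraction, degree-model selection, dimension, small-world metrics and
robustness perturbations — writing diffable TSV/JSON reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from . import graph_core, model_selection, small_world, topo_dimension
from .graph_core import Graph

logger = logging.getLogger("connectopo")

__all__ = ["ScalingFit", "fit_offset_power", "fit_shifted_power_growth",
           "zero_slope_test", "analyze_graph"]


@dataclass
class ScalingFit:
    model: str                       # "offset_power" | "shifted_power_growth"
    params: tuple[float, float, float]
    residual_sse: float
    param_stderr: tuple[float, float, float]
    degenerate: bool = False


def _fit_power_form(x: np.ndarray, y: np.ndarray, model: str,
                    c_grid: np.ndarray) -> ScalingFit:
    """Shared machinery for y = a + b*x^c (deterministic multi-start in c).

    For each trial exponent the (a, b) pair is solved linearly, then the
    best start is polished with full nonlinear least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (x, y) points")
    if np.any(x <= 0):
        raise ValueError("x must be positive")

    def f(x, a, b, c):
        return a + b * np.power(x, c)

    best = None
    for c0 in c_grid:
        X = np.column_stack([np.ones_like(x), np.power(x, c0)])
        (a0, b0), sse, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((X @ [a0, b0] - y) ** 2).sum())
        if best is None or sse < best[3]:
            best = (a0, b0, c0, sse)
    a0, b0, c0, _ = best
    try:
        popt, pcov = optimize.curve_fit(f, x, y, p0=[a0, b0, c0],
                                        maxfev=20000)
        sse = float(((f(x, *popt) - y) ** 2).sum())
        stderr = tuple(float(s) for s in np.sqrt(np.maximum(np.diag(pcov), 0)))
    except RuntimeError as exc:
        raise RuntimeError(f"scaling fit did not converge: {exc}") from exc
    a, b, c = (float(p) for p in popt)
    # degenerate when the power term is indistinguishable from a constant
    spread = float(np.ptp(y)) or 1.0
    degenerate = (abs(b) * float(np.ptp(np.power(x, c))) < 1e-8 * spread
                  or (np.isfinite(stderr[2]) and stderr[2] >= abs(c)
                      and abs(b) * abs(np.power(x, c)).max() < 0.01 * spread))
    return ScalingFit(model, (a, b, c), sse, stderr, degenerate)


def _fit_fixed_exponent(x, y, model: str, c: float) -> ScalingFit:
    """With the exponent pinned the model is ordinary linear regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), np.power(x, c)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = X @ coef - y
    sse = float((resid ** 2).sum())
    dof = max(x.size - 2, 1)
    cov = np.linalg.inv(X.T @ X) * sse / dof
    se = np.sqrt(np.maximum(np.diag(cov), 0))
    return ScalingFit(model, (float(coef[0]), float(coef[1]), float(c)),
                      sse, (float(se[0]), float(se[1]), 0.0))


def fit_offset_power(x, y, fix_exponent: float | None = None) -> ScalingFit:
    """Least squares for ``y = a + b x^c`` (x typically 1/N), multi-start
    over ``c`` in {0.1, 0.2, ..., 2.0}; ``fix_exponent`` pins c (the model
    is then plain linear regression in x^c)."""
    if fix_exponent is not None:
        return _fit_fixed_exponent(x, y, "offset_power", fix_exponent)
    return _fit_power_form(np.asarray(x, float), np.asarray(y, float),
                           "offset_power", np.arange(0.1, 2.01, 0.1))


def fit_shifted_power_growth(N, y, fix_exponent: float | None = None) -> ScalingFit:
    """Least squares for ``y = A + B N^C`` (growth of an invariant with
    size); the exponent start grid covers slow growth, C in {0.05..1.5}."""
    if fix_exponent is not None:
        return _fit_fixed_exponent(N, y, "shifted_power_growth", fix_exponent)
    return _fit_power_form(np.asarray(N, float), np.asarray(y, float),
                           "shifted_power_growth",
                           np.arange(0.05, 1.51, 0.05))


def zero_slope_test(x, y, log_transform: bool = False) -> tuple[float, float]:
    """Two-sided t-test that the regression slope of y on x is zero.

    With ``log_transform`` both series are log-transformed first.  A
    strictly constant y returns slope 0 with p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log transform requires positive data")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# End-to-end orchestration


@dataclass
class AnalysisConfig:
    """Run configuration for the end-to-end pipeline."""

    graph_path: str | None = None
    graph: Graph | None = None
    out_dir: str = "connectopo_out"
    stages: tuple[str, ...] = ("degree", "dimension", "smallworld")
    seed: int = 0
    families: tuple[str, ...] = model_selection.FAMILIES
    kc_grid: list[int] | None = None
    criterion: str = "aicc"
    L_mode: str = "auto"
    r_max: int | None = None
    dimension_fit_range: object = "auto"
    robustness: bool = False
    robustness_dimension_fraction: float = 0.20   # directed-view removal
    robustness_smallworld_fraction: float = 0.10  # undirected removal

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        """Plain key=value text (lists comma-separated) or JSON."""
        text = Path(path).read_text()
        try:
            data = json.loads(text)
        except json.JSONDecodeError:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, val = (t.strip() for t in line.split("=", 1))
                data[key] = val
        kwargs: dict = {}
        for key, val in data.items():
            if key in ("stages", "families") and isinstance(val, str):
                kwargs[key] = tuple(t.strip() for t in val.split(","))
            elif key == "kc_grid" and isinstance(val, str):
                kwargs[key] = [int(t) for t in val.split(",")]
            elif key in ("seed", "r_max"):
                kwargs[key] = int(val)
            elif key == "robustness":
                kwargs[key] = str(val).lower() in ("1", "true", "yes")
            elif key.endswith("fraction"):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def _degree_stage(g: Graph, cfg: AnalysisConfig, out: Path) -> dict:
    hist = graph_core.degree_histogram(g)
    hist.to_tsv(out / "degree_histogram.tsv")
    fits = {}
    for fam in cfg.families:
        try:
            fits[fam] = model_selection.scan_cutoff(
                hist, fam, kc_grid=cfg.kc_grid, criterion=cfg.criterion)
        except (RuntimeError, ValueError) as exc:
            logger.warning("degree stage: %s fit failed (%s)", fam, exc)
    table = model_selection.delta_table(fits, criterion=cfg.criterion)
    with open(out / "degree_fits.json", "w") as fh:
        json.dump(table.to_dict(), fh, indent=1)
    with open(out / "degree_deltas.tsv", "w") as fh:
        fh.write("family\tdelta\tk_c\tK\tlogL\n")
        for fam in cfg.families:
            if fam in table.deltas:
                fit = table.rows[fam]
                fh.write(f"{fam}\t{table.deltas[fam]:.4f}\t{fit.k_c}"
                         f"\t{fit.K}\t{fit.logL:.4f}\n")
    with open(out / "degree_params.tsv", "w") as fh:
        fh.write("family\tk_c\t" + "\t".join(
            ["alpha", "beta", "gamma", "mu", "s"]) + "\n")
        for fam, fit in table.rows.items():
            s = fit.spec.shape
            vals = [s.get(p, float("nan"))
                    for p in ("alpha", "beta", "gamma", "mu", "s")]
            fh.write(f"{fam}\t{fit.k_c}\t"
                     + "\t".join(f"{v:.6g}" for v in vals) + "\n")
    return table.to_dict()


def _dimension_stage(g: Graph, cfg: AnalysisConfig, out: Path,
                     tag: str = "dimension") -> dict:
    curve = topo_dimension.ball_growth(g, r_max=cfg.r_max, seed=cfg.seed)
    est = topo_dimension.fit_dimension(curve, fit_range=cfg.dimension_fit_range)
    d_eff = topo_dimension.effective_dimension(curve)
    de_map = {int(row[0] - 0.5): row[1] for row in d_eff}
    with open(out / f"{tag}.tsv", "w") as fh:
        fh.write("r\tmean_ball\tD_eff\n")
        for r, nb in zip(curve.r_values, curve.mean_ball):
            de = de_map.get(int(r), float("nan"))
            fh.write(f"{r}\t{nb:.6g}\t{de:.6g}\n")
    result = {"D": est.D, "stderr": est.stderr, "fit_range": est.fit_range,
              "prefactor": est.prefactor, "n_seeds": curve.n_seeds,
              "seed_mode": curve.seed_mode}
    with open(out / f"{tag}.json", "w") as fh:
        json.dump(result, fh, indent=1)
    return result


def _smallworld_stage(g: Graph, cfg: AnalysisConfig, out: Path,
                      tag: str = "smallworld") -> dict:
    rep = small_world.small_world_report(g, L_mode=cfg.L_mode, seed=cfg.seed)
    with open(out / f"{tag}.json", "w") as fh:
        json.dump(rep.to_dict(), fh, indent=1)
    with open(out / f"{tag}.tsv", "w") as fh:
        fh.write("\t".join(rep.TSV_COLUMNS) + "\n")
        fh.write(rep.to_tsv_row() + "\n")
    return rep.to_dict()


def analyze_graph(config: AnalysisConfig | dict) -> dict:
    """Run the configured stages on one graph and write a report bundle.

    Stages run on the largest connected component.  With ``robustness`` on,
    dimension is re-measured after removing 20% of directed edge views and
    the small-world metrics after removing 10% of undirected edges.  Any
    stage failure aborts with the stage name and cause.  Reruns with the
    same config and seeds are byte-identical.
    """
    cfg = AnalysisConfig(**config) if isinstance(config, dict) else config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.graph is not None:
        g = cfg.graph
    elif cfg.graph_path:
        g = graph_core.read_edge_list(cfg.graph_path)
    else:
        raise ValueError("config must name a graph or graph_path")
    g = graph_core.largest_connected_component(g)
    bundle: dict = {"config": {k: v for k, v in vars(cfg).items()
                               if k != "graph"},
                    "n_nodes": g.n_nodes, "n_edges": g.n_edges}
    timings: dict[str, float] = {}
    stage_fns = {"degree": _degree_stage, "dimension": _dimension_stage,
                 "smallworld": _smallworld_stage}
    for stage in cfg.stages:
        if stage not in stage_fns:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        try:
            bundle[stage] = stage_fns[stage](g, cfg, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", stage, timings[stage])
    if cfg.robustness:
        t0 = time.perf_counter()
        try:
            if "dimension" in cfg.stages:
                gd = graph_core.remove_random_edges(
                    g, cfg.robustness_dimension_fraction,
                    mode="directed_views", seed=cfg.seed)
                gd = graph_core.largest_connected_component(gd)
                bundle["dimension_perturbed"] = _dimension_stage(
                    gd, cfg, out, tag="dimension_perturbed")
            if "smallworld" in cfg.stages:
                gs = graph_core.remove_random_edges(
                    g, cfg.robustness_smallworld_fraction,
                    mode="undirected", seed=cfg.seed)
                gs = graph_core.largest_connected_component(gs)
                bundle["smallworld_perturbed"] = _smallworld_stage(
                    gs, cfg, out, tag="smallworld_perturbed")
        except Exception as exc:
            raise RuntimeError(f"stage 'robustness' failed: {exc}") from exc
        timings["robustness"] = time.perf_counter() - t0
    bundle["timings"] = timings
    with open(out / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    return bundle
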