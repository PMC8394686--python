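"""End-to-end inference: panel in, significant causal graph out."""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .dpc import dpc_analysis
from .network import CausalGraph
from .rpdc import compute_rpdc, default_grid, rpdc_significance
from .var import TimeSeriesPanel, fit_var, select_order

__all__ = ["choose_order", "infer_graph", "make_inferrer"]


def choose_order(panel: TimeSeriesPanel, config: RunConfig) -> int:
    if config.order_criterion == "fixed":
        return config.order
    return select_order(panel, config.p_max, criterion=config.order_criterion)


def infer_graph(
    panel: TimeSeriesPanel,
    config: RunConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> CausalGraph:
    """Run the configured method (rPDC or DPC) on a panel.

    ``seed`` overrides the configured seed; it only matters for the DPC
    surrogate bootstrap — the rPDC path is deterministic given the data.
    """
    if config.center:
        values = panel.values - panel.values.mean(axis=0)
        panel = TimeSeriesPanel(values, panel.labels)
    p = choose_order(panel, config)
    if config.method == "rpdc":
        fit = fit_var(panel, p, sigma_divisor=config.sigma_divisor)
        result = compute_rpdc(fit, default_grid(config.n_freq), alpha=config.alpha)
        return rpdc_significance(result, rule=config.rule, fraction=config.fraction)
    _res, _ci, graph = dpc_analysis(
        panel,
        p,
        B=config.B,
        alpha=config.alpha,
        seed=config.seed if seed is None else seed,
        bonferroni=config.bonferroni,
        max_iter=config.surrogate_max_iter,
    )
    return graph


def make_inferrer(config: RunConfig, seed: int | None = None):
    """Inference callback for the sub-network scan.

    Each invocation consumes the next child of a seed sequence so that
    successive scan steps use independent surrogate draws while the whole
    scan stays reproducible from the single seed.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    stream = iter(ss.spawn(config.max_depth + 1))

    def infer(panel: TimeSeriesPanel) -> CausalGraph:
        return infer_graph(panel, config, seed=next(stream))

    return infer
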