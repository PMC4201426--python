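"""End-to-end analysis pipeline.

Runs, in order, on a (tree, status, traits) input triple:

1. input parsing, name matching, and tree/table intersection (all drops
   logged with counts);
2. taxon-selectivity randomization at family and order level;
3. the D statistic for the prohibited/nonprohibited trait;
4. NRI/NTI per invasion category against the phylogeny-pool null;
5. Wilcoxon comparisons of ED and BL across category pairs;
6. the univariate GLMM screen with the redundancy filter.

A master seed deterministically spawns one RNG stream per stochastic
stage, so disabling one stage does not change another's draws, and the
same configuration and seed reproduce byte-identical outputs.  Results
are written as plain TSV/JSON into the output directory:
``selectivity.tsv``, ``dstat.json``, ``community.tsv``,
``comparisons.tsv``, ``glmm.tsv``, ``retained_predictors.json``, plus
``run.log``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import community_by_category
from .compare import DEFAULT_PAIRS, compare_categories
from .dstat import d_statistic, interpret_d
from .glmm import screen_traits
from .phylo import read_newick
from .selectivity import selectivity_test
from .tables import parse_status, parse_traits

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage precondition failed; the message names the stage."""


@dataclass
class RunConfig:
    tree: str | Path
    status: str | Path
    outdir: str | Path
    seed: int
    traits: str | Path | None = None
    n_reps: int = 1000
    n_sims: int = 1000
    alpha: float = 0.05
    corr_threshold: float = 0.7
    missing_sentinel: float = -999.0
    min_complete_cases: int = 10
    resolve_polytomies: bool = False
    plots: bool = False
    stages: dict[str, bool] = field(default_factory=lambda: {
        "selectivity": True, "dstat": True, "community": True,
        "compare": True, "glmm": True,
    })


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["selectivity", "dstat", "community", "glmm"]
    ss = np.random.SeedSequence(seed)
    return {n: int(c.generate_state(1)[0] % (2**31))
            for n, c in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns a dict of result objects and paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("invade")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    outputs: dict = {"outdir": outdir}
    try:
        log.info("invade %s | seed=%d n_reps=%d n_sims=%d alpha=%g",
                 __version__, config.seed, config.n_reps, config.n_sims,
                 config.alpha)
        seeds = _stage_seeds(config.seed)

        # ---- stage 0: inputs ---------------------------------------- #
        tree = read_newick(config.tree)
        status = parse_status(config.status)
        traits = (parse_traits(config.traits, config.missing_sentinel)
                  if config.traits else None)
        tips = set(tree.tip_names)
        in_tree = [s for s in status.species if s in tips]
        log.info("inputs: %d tree tips, %d status rows, %d matched",
                 tree.n_tips, len(status.species), len(in_tree))
        if len(in_tree) < 3:
            raise PipelineError("input stage: fewer than 3 status species "
                                "match the tree tips")
        status_tree = status.restrict_to(in_tree)
        analysis_tree = tree.restrict_to(in_tree) if len(in_tree) < tree.n_tips else tree
        if int(status.data["y"].sum()) == 0:
            raise PipelineError("selectivity stage precondition: the status "
                                "table contains zero prohibited species")
        metrics = analysis_tree.tip_metrics()
        metrics.to_csv(outdir / "tip_metrics.tsv", sep="\t",
                       float_format=_FLOAT_FMT)
        outputs["metrics"] = metrics

        # ---- stage 1: taxon selectivity ----------------------------- #
        if config.stages.get("selectivity", True):
            parts = [selectivity_test(status, level, n_reps=config.n_reps,
                                      seed=seeds["selectivity"] + i)
                     for i, level in enumerate(("family", "order"))]
            sel = pd.concat(parts, ignore_index=True)
            sel.to_csv(outdir / "selectivity.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
            outputs["selectivity"] = sel

        # ---- stage 2: phylogenetic signal (D) ----------------------- #
        if config.stages.get("dstat", True):
            try:
                result = d_statistic(analysis_tree, status_tree.y,
                                     n_sims=config.n_sims, seed=seeds["dstat"],
                                     resolve_polytomies=config.resolve_polytomies)
            except ValueError as exc:
                raise PipelineError(f"dstat stage: {exc}") from exc
            payload = result.to_dict()
            payload["interpretation"] = interpret_d(result, config.alpha)
            (outdir / "dstat.json").write_text(json.dumps(payload, indent=2,
                                                          sort_keys=True) + "\n")
            log.info("D = %.4f (p_random=%.4g, p_brownian=%.4g): %s",
                     result.d_value, result.p_random, result.p_brownian,
                     payload["interpretation"])
            outputs["dstat"] = result

        # ---- stage 3: NRI / NTI ------------------------------------- #
        if config.stages.get("community", True):
            com = community_by_category(analysis_tree, status_tree,
                                        n_reps=config.n_reps,
                                        seed=seeds["community"])
            com.to_csv(outdir / "community.tsv", sep="\t", index=False,
                       float_format=_FLOAT_FMT)
            outputs["community"] = com

        # ---- stage 4: ED / BL comparisons --------------------------- #
        if config.stages.get("compare", True):
            parts = [compare_categories(metrics, status_tree, metric=m,
                                        pairs=DEFAULT_PAIRS)
                     for m in ("ED", "BL")]
            comp = pd.concat(parts, ignore_index=True)
            comp.to_csv(outdir / "comparisons.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
            outputs["comparisons"] = comp

        # ---- stage 5: GLMM screen ----------------------------------- #
        if config.stages.get("glmm", True):
            screen = screen_traits(status, traits=traits, metrics=metrics,
                                   alpha=config.alpha,
                                   corr_threshold=config.corr_threshold,
                                   min_n=config.min_complete_cases)
            screen.results.to_csv(outdir / "glmm.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
            (outdir / "retained_predictors.json").write_text(json.dumps({
                "alpha": screen.alpha,
                "corr_threshold": screen.corr_threshold,
                "significant": screen.significant,
                "retained": screen.retained,
                "skipped": screen.skipped,
            }, indent=2, sort_keys=True) + "\n")
            outputs["glmm"] = screen

        if config.plots:
            _write_plots(outputs, outdir)
    finally:
        handler.close()
        root.removeHandler(handler)
    return outputs


def _write_plots(outputs: dict, outdir: Path) -> None:
    """Optional summary graphics: selectivity bars and ED box plots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "selectivity" in outputs:
        sel = outputs["selectivity"]
        fam = sel[sel["level"] == "family"]
        fig, ax = plt.subplots(figsize=(8, 4))
        xs = np.arange(len(fam))
        ax.bar(xs - 0.2, fam["observed_pct"], width=0.4, label="observed")
        ax.bar(xs + 0.2, fam["null_mean_pct"], width=0.4, label="null mean")
        ax.set_xticks(xs, fam["taxon"], rotation=90, fontsize=7)
        ax.set_ylabel("% prohibited of all species")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "selectivity.png", dpi=150)
        plt.close(fig)
    if "metrics" in outputs and "comparisons" in outputs:
        metrics = outputs["metrics"]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.boxplot([metrics["ED"], metrics["BL"]], tick_labels=["ED", "BL"])
        ax.set_ylabel("Myr")
        fig.tight_layout()
        fig.savefig(outdir / "metrics.png", dpi=150)
        plt.close(fig)
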