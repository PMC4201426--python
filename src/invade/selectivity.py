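"""Taxon-selectivity randomization test.

Asks whether a family (or order) contains more or fewer prohibited
species than expected by chance.  With *n* prohibited species among *N*
analyzed species, the observed proportion for a taxon is
``100 * (# prohibited in taxon) / N``.  The null draws ``n_reps`` random
assemblages of *n* distinct species from the full species pool and
recomputes the same proportion; a taxon is flagged over-/under-
represented when its observed proportion falls outside the empirical
95% interval of the null proportions.  (The null count in a taxon of
size *m* is hypergeometric with mean ``n*m/N`` — the calibration check
used in the tests.)
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import StatusTable

__all__ = ["SelectivityResult", "selectivity_test"]

log = logging.getLogger(__name__)


@dataclass
class SelectivityResult:
    taxon: str
    level: str
    n_in_taxon: int
    n_prohibited_in_taxon: int
    observed_pct: float
    null_mean_pct: float
    ci_low: float
    ci_high: float
    verdict: str  # over | under | ns
    n_reps: int


def selectivity_test(status: StatusTable, level: str = "family",
                     n_reps: int = 1000, seed: int | None = None,
                     ci: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Run the randomization test at one taxonomic level.

    Returns one row per taxon with the observed proportion, the null mean
    and percentile interval, and a verdict (``over``/``under``/``ns``:
    observed above, below, or inside the interval).
    """
    if level not in ("family", "order"):
        raise ValueError("level must be 'family' or 'order'")
    df = status.data
    n_total = len(df)
    n_prohibited = int(df["y"].sum())
    if n_prohibited == 0:
        raise ValueError("selectivity test requires at least one prohibited species")
    taxa = df[level].astype(str)
    if taxa.nunique() < 2:
        raise ValueError(f"selectivity test requires >= 2 taxa at level {level!r}")
    if n_reps < 100:
        warnings.warn(f"n_reps={n_reps} < 100 gives a coarse null interval",
                      UserWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    # membership matrix: taxa x species
    taxon_names = sorted(taxa.unique())
    member = np.stack([(taxa == t).to_numpy() for t in taxon_names]).astype(float)

    # n_reps assemblages of n_prohibited distinct species: top-n of random keys
    keys = rng.random((n_reps, n_total))
    picks = np.argpartition(keys, n_prohibited - 1, axis=1)[:, :n_prohibited]
    indicator = np.zeros((n_total, n_reps))
    indicator[picks.T, np.arange(n_reps)[None, :]] = 1.0
    null_counts = member @ indicator                     # (taxa, reps)
    null_pct = 100.0 * null_counts / n_total

    lo, hi = np.percentile(null_pct, ci, axis=1)
    null_mean = null_pct.mean(axis=1)
    obs_counts = df.groupby(taxa)["y"].sum().reindex(taxon_names).to_numpy()
    sizes = taxa.value_counts().reindex(taxon_names).to_numpy()
    obs_pct = 100.0 * obs_counts / n_total

    verdict = np.where(obs_pct > hi, "over", np.where(obs_pct < lo, "under", "ns"))
    rows = [
        SelectivityResult(t, level, int(sizes[i]), int(obs_counts[i]),
                          float(obs_pct[i]), float(null_mean[i]),
                          float(lo[i]), float(hi[i]), str(verdict[i]), n_reps)
        for i, t in enumerate(taxon_names)
    ]
    log.info("selectivity (%s): %d taxa, %d over, %d under", level, len(rows),
             int((verdict == "over").sum()), int((verdict == "under").sum()))
    return pd.DataFrame([r.__dict__ for r in rows])
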