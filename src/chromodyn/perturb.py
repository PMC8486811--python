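"""Differential-activity analysis of in-silico perturbations.

Conditions (wild type vs knockout / loops / heterochromatin island /
deletion) are compared TU-by-TU with a two-sample two-sided Student t-test
on per-run activities.  Global effects are summarised by the
"transcriptional difference", a Euclidean distance between the two mean
activity vectors.  No multiple-testing correction is applied internally;
significance thresholds are report-time parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .params import ConfigurationError


@dataclass(frozen=True)
class PerturbationResult:
    tu_indices: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    effect: np.ndarray       # mean_b - mean_a
    t_stat: np.ndarray
    p: np.ndarray            # two-sided; NaN where variance is zero in both arms
    transcriptional_diff: float
    genomic_positions: np.ndarray | None = None  # bin midpoints (bp)

    def significant(self, p_threshold: float = 0.05) -> np.ndarray:
        """Mask of TUs whose change is significant at the given raw threshold."""
        with np.errstate(invalid="ignore"):
            return np.asarray(self.p < p_threshold)

    def to_frame(self):
        import pandas as pd

        data = {"tu_index": self.tu_indices, "activity_a": self.mean_a,
                "activity_b": self.mean_b, "effect": self.effect,
                "t": self.t_stat, "p": self.p}
        if self.genomic_positions is not None:
            data["position_bp"] = self.genomic_positions
        return pd.DataFrame(data)


def transcriptional_difference(mean_a: np.ndarray, mean_b: np.ndarray,
                               exclude_index: int | None = None) -> float:
    """Euclidean distance between two per-TU mean-activity vectors.

    When comparing a knockout against wild type, the mutated TU itself is
    excluded (``exclude_index`` is its position in the vectors) so that the
    statistic isolates trans effects.
    """
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ConfigurationError("activity vectors must have equal length")
    mask = np.ones(a.shape[0], dtype=bool)
    if exclude_index is not None:
        mask[exclude_index] = False
    return float(np.sqrt(np.sum((a[mask] - b[mask]) ** 2)))


def differential_activity(runs_a: np.ndarray, runs_b: np.ndarray,
                          tu_indices: np.ndarray | None = None,
                          exclude_index: int | None = None,
                          genomic_positions: np.ndarray | None = None,
                          equal_var: bool = True) -> PerturbationResult:
    """Per-TU Student t-test between two run ensembles.

    ``runs_a``/``runs_b`` are (run x TU) per-run activity matrices with
    matched TU columns; each needs >= 3 runs.  TUs with zero variance in
    both arms get p = NaN (flagged missing; identical constant arms are not
    evidence either way).
    """
    a = np.atleast_2d(np.asarray(runs_a, dtype=float))
    b = np.atleast_2d(np.asarray(runs_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ConfigurationError("mismatched TU sets between conditions")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ConfigurationError("need at least 3 runs per condition")
    n_tu = a.shape[1]
    if tu_indices is None:
        tu_indices = np.arange(n_tu)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p = stats.ttest_ind(b, a, axis=0, equal_var=equal_var)
    degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
    t_stat = np.where(degenerate, np.nan, t_stat)
    p = np.where(degenerate, np.nan, p)
    diff = transcriptional_difference(mean_a, mean_b, exclude_index)
    return PerturbationResult(np.asarray(tu_indices), mean_a, mean_b,
                              mean_b - mean_a, t_stat, p, diff,
                              genomic_positions)


def knockout_sweep(fibre, sim_config, base_seed: int, n_runs: int,
                   wildtype_runs: np.ndarray | None = None,
                   p_threshold: float = 0.05):
    """Knock out each recorded TU in turn and quantify the global effect.

    Shares seeds between conditions for variance reduction: mutant run i
    uses the same seed as wild-type run i.  Returns a DataFrame with one row
    per TU: its wild-type activity, the transcriptional difference of its
    knockout, and the number of significantly changed other TUs.
    """
    import pandas as pd

    from .dynamics import run_ensemble
    from .fibre import knockout_tu
    from .transcription import per_run_activity_matrix

    if wildtype_runs is None:
        wt_results = run_ensemble(fibre, sim_config, base_seed, n_runs, "wt")
        wildtype_runs = per_run_activity_matrix([r.record for r in wt_results])
    tus = fibre.tu_indices
    rows = []
    for k, tu in enumerate(tus):
        mutant = knockout_tu(fibre, int(tu))
        res = run_ensemble(mutant, sim_config, base_seed, n_runs, f"ko{tu}")
        mut_runs = per_run_activity_matrix([r.record for r in res])
        result = differential_activity(wildtype_runs, mut_runs,
                                       tu_indices=tus, exclude_index=k)
        others = np.ones(len(tus), dtype=bool)
        others[k] = False
        n_sig = int(np.nansum(result.significant(p_threshold)[others]))
        rows.append({"tu_index": int(tu),
                     "wt_activity": float(wildtype_runs.mean(axis=0)[k]),
                     "transcriptional_difference": result.transcriptional_diff,
                     "n_significant": n_sig})
    return pd.DataFrame(rows)


def manhattan_qq(result: PerturbationResult,
                 positions: np.ndarray | None = None):
    """Manhattan and QQ series for a mapped perturbation (deletion analyses).

    Manhattan: (position in Mbp, -log10 p) per TU.  QQ: sorted observed
    -log10 p against -log10 of uniform-order-statistic quantiles
    (k - 0.5)/n -- the null in which activity changes are pure noise, so
    normal-theory t-test p-values are uniform.
    """
    if positions is None:
        positions = result.genomic_positions
    if positions is None:
        raise ConfigurationError("genomic positions required for Manhattan plot")
    positions = np.asarray(positions, dtype=float)
    p = np.asarray(result.p, dtype=float)
    ok = ~np.isnan(p)
    manhattan = np.column_stack([positions[ok] / 1e6, -np.log10(p[ok])])
    obs = np.sort(-np.log10(p[ok]))[::-1]
    n = obs.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = np.column_stack([expected, obs])
    return manhattan, qq


def write_manhattan_qq_tsv(manhattan: np.ndarray, qq: np.ndarray,
                           manhattan_path, qq_path) -> None:
    """Plain-TSV export of the two series for any plotting layer."""
    np.savetxt(manhattan_path, manhattan, delimiter="\t", fmt="%.6f",
               header="position_mbp\tneg_log10_p", comments="")
    np.savetxt(qq_path, qq, delimiter="\t", fmt="%.6f",
               header="expected_neg_log10_p\tobserved_neg_log10_p", comments="")


def write_result_tsv(result: PerturbationResult, path, fibre=None) -> None:
    df = result.to_frame()
    if fibre is not None and fibre.genomic_map is not None:
        chrom, starts, ends = fibre.genomic_map
        df.insert(1, "chrom", chrom)
        df.insert(2, "start", np.asarray(starts)[result.tu_indices])
        df.insert(3, "end", np.asarray(ends)[result.tu_indices])
    df.to_csv(path, sep="\t", index=False)
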