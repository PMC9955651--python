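"""End-to-end cohort analysis: measures over trials, then statistics.

Glue that applies a selected measure battery to each (subject, trial)
series of a cohort, collects a long-format TrialTable, and runs the
Friedman / Conover / direction-count machinery over it.  Used by the
examples, the CLI and the acceptance runs.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np

from . import fractal, hra, pentropy
from .sigio import EventSeries, TrialTable
from .stats import conover_posthoc, direction_counts, friedman_kendall
from .synth import SubjectRecord

__all__ = ["MEASURES", "measure_series", "cohort_table", "trial_statistics",
           "select_rbr_labels"]


def select_rbr_labels(records: Sequence[SubjectRecord],
                      fs_resample: float = 4.0) -> dict[int, str]:
    """Run the RBA scorecard per subject and return subject -> RBR label."""
    from .spectral import RBAScorecard, score_trial, select_rbr, PACED_TRIALS

    labels = {}
    for rec in records:
        scores = {lab: score_trial(rec.trials[lab][0], fs_resample=fs_resample)
                  for lab in PACED_TRIALS if lab in rec.trials}
        card = RBAScorecard(trials=scores)
        labels[rec.subject] = select_rbr(card)
    return labels


def _vals(x: EventSeries) -> np.ndarray:
    return np.asarray(x.intervals, dtype=float)


#: Default measure battery: name -> callable on an RRi EventSeries.
MEASURES: Mapping[str, Callable[[EventSeries], float]] = {
    "FD_H": lambda x: fractal.fd_higuchi(_vals(x), kmax=8).value,
    "FD_K": lambda x: fractal.fd_katz(_vals(x)).value,
    "FD_C": lambda x: fractal.fd_castiglioni(_vals(x)).value,
    "FD_P": lambda x: fractal.fd_petrosian(_vals(x), "b").value,
    "FD_S": lambda x: fractal.fd_sevcik(_vals(x)).value,
    "mFD_M": lambda x: fractal.fd_maragos(_vals(x), scales=[1, 2, 3, 4, 6, 8]).value,
    "SD1": lambda x: hra.lagged_poincare(x, 1).sd1,
    "SD2": lambda x: hra.lagged_poincare(x, 1).sd2,
    "GI": lambda x: hra.classical_indices(x)[1],
    "PI": lambda x: hra.classical_indices(x)[2],
    "SDNNup": lambda x: hra.asymmetry_decomposition(x).sdnn_up,
    "SDNNdown": lambda x: hra.asymmetry_decomposition(x).sdnn_down,
    "PE": lambda x: pentropy.permutation_entropy(_vals(x), m=3, tau=1),
    "CPEI": lambda x: pentropy.cpei(_vals(x)),
}


def measure_series(x: EventSeries,
                   measures: Mapping[str, Callable] | None = None
                   ) -> dict[str, float]:
    """Apply the measure battery to one interval series."""
    measures = measures or MEASURES
    out = {}
    for name, fn in measures.items():
        try:
            out[name] = float(fn(x))
        except ValueError:
            out[name] = np.nan
    return out


def cohort_table(records: Sequence[SubjectRecord],
                 measures: Mapping[str, Callable] | None = None,
                 duration_min: float = 5.0,
                 rbr_labels: Mapping[int, str] | None = None) -> TrialTable:
    """Long-format measure table over a cohort.

    When ``rbr_labels`` maps subject -> selected trial label, a
    composite "RBR" trial (copy of that subject's selected paced trial)
    is appended per subject.
    """
    table = TrialTable()
    rows = []
    for rec in records:
        trial_values = {}
        for label, (rri, _rsp) in rec.trials.items():
            vals = measure_series(rri, measures)
            trial_values[label] = vals
            for m, v in vals.items():
                rows.append({"participant": rec.subject, "trial": label,
                             "duration": duration_min, "measure_id": m,
                             "value": v})
        if rbr_labels is not None:
            chosen = rbr_labels[rec.subject]
            for m, v in trial_values[chosen].items():
                rows.append({"participant": rec.subject, "trial": "RBR",
                             "duration": duration_min, "measure_id": m,
                             "value": v})
    return TrialTable.from_records(rows)


def trial_statistics(table: TrialTable, measure_id: str,
                     trials: Sequence[str] | None = None) -> dict:
    """Friedman + Kendall W, Conover pairs, and Baseline-vs-last-trial
    direction counts for one measure of a TrialTable."""
    wide = table.pivot(measure_id)
    if trials is not None:
        wide = wide[list(trials)]
    data = wide.to_numpy()
    if np.isnan(data).any():
        raise ValueError(f"missing cells for measure {measure_id}")
    fr = friedman_kendall(data)
    labels = list(wide.columns)
    posthoc = conover_posthoc(data, labels=labels)
    out = {"friedman": fr, "conover": posthoc, "labels": labels}
    if "Baseline" in labels:
        other = labels[-1] if labels[-1] != "Baseline" else labels[0]
        ups, downs, zeros, prop, consistent = direction_counts(
            wide["Baseline"].to_numpy(), wide[other].to_numpy())
        out["direction"] = {"pair": ("Baseline", other), "ups": ups,
                            "downs": downs, "zeros": zeros,
                            "proportion": prop, "consistent": consistent}
    return out
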