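"""Compound-level calls, contingency tables and sensitivity/specificity.

A compound is positive in the zebrafish model when any numeric feature is
significant or any binary flag reaches 30 % incidence among its larvae; in
the cardiomyocyte model when any feature is significant at any time point.
Calls are cross-compared with clinical (human) labels in 2x2 contingency
tables with TPR = TP/(TP+FN) and TNR = TN/(TN+FP), overall and within the
therapeutic subgroups Cardio (first-level ATC code C), Neuro (N) and Other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

#: Binary-flag incidence threshold (percent of larvae carrying the flag).
INCIDENCE_THRESHOLD = 30.0


def flag_incidence(flags, threshold: float = INCIDENCE_THRESHOLD) -> tuple[float, bool]:
    """Incidence (%) of a binary flag across subjects and the call.

    The call is positive when incidence is greater than or equal to the
    threshold (default 30 %).
    """
    flags = list(flags)
    if not flags:
        raise ValueError("need at least one subject")
    incidence = 100.0 * sum(bool(f) for f in flags) / len(flags)
    return incidence, incidence >= threshold


@dataclass
class CompoundCall:
    """Overall positive/negative call for one compound in one model."""

    compound: str
    model: str  # "zebrafish" or "hipsc"
    positive: bool
    triggered_by: tuple[str, ...]


def compound_call(
    compound: str,
    feature_calls: dict[str, bool],
    flag_incidences: dict[str, float] | None = None,
    model: str = "zebrafish",
    threshold: float = INCIDENCE_THRESHOLD,
) -> CompoundCall:
    """Combine per-feature calls (and flag incidences) into one call.

    Zebrafish: positive if any numeric feature call is true or any flag
    incidence reaches the threshold.  Cardiomyocyte model: positive if any
    feature is called at any time point (the keys of ``feature_calls`` then
    carry the time point).
    """
    if not feature_calls and not flag_incidences:
        raise ValueError("empty call set")
    triggers = [f for f, c in feature_calls.items() if c]
    if model == "zebrafish" and flag_incidences:
        triggers += [
            f for f, inc in flag_incidences.items() if inc >= threshold
        ]
    return CompoundCall(
        compound=compound,
        model=model,
        positive=bool(triggers),
        triggered_by=tuple(sorted(triggers)),
    )


@dataclass
class ContingencyResult:
    """2x2 cross-comparison of model calls against human labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        """Sensitivity TP/(TP+FN), as a percentage."""
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def tnr(self) -> float:
        """Specificity TN/(TN+FP), as a percentage."""
        return 100.0 * self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def tpr_reported(self) -> int:
        return round_half_up(self.tpr)

    @property
    def tnr_reported(self) -> int:
        return round_half_up(self.tnr)


def round_half_up(x: float) -> int:
    """Round a percentage to an integer with ties going up."""
    import math

    return int(math.floor(x + 0.5))


def contingency(
    calls: dict[str, bool],
    human_labels: dict[str, bool],
    subset: set[str] | None = None,
) -> ContingencyResult:
    """Tally TP/FP/TN/FN of model calls against human labels.

    Raises on any compound without a human label.
    """
    names = sorted(calls) if subset is None else sorted(set(calls) & subset)
    missing = [c for c in names if c not in human_labels]
    if missing:
        raise ValueError(f"compounds without human label: {missing}")
    tp = fp = tn = fn = 0
    for c in names:
        called, truth = calls[c], human_labels[c]
        if called and truth:
            tp += 1
        elif called and not truth:
            fp += 1
        elif not called and truth:
            fn += 1
        else:
            tn += 1
    return ContingencyResult(tp, fp, tn, fn)


def withdrawn_sensitivity(calls: dict[str, bool], withdrawn: set[str]) -> float:
    """Detected fraction (%) among market-withdrawn compounds."""
    if not withdrawn:
        raise ValueError("withdrawn set is empty")
    hits = sum(bool(calls.get(c, False)) for c in withdrawn)
    return 100.0 * hits / len(withdrawn)


def assign_subgroup(atc_code: str | None) -> str:
    """Therapeutic subgroup from the first ATC level: C -> Cardio,
    N -> Neuro, anything else (or missing) -> Other."""
    if not atc_code or not str(atc_code).strip():
        warnings.warn("missing ATC code; assigning subgroup Other")
        return "Other"
    first = str(atc_code).strip()[0].upper()
    return {"C": "Cardio", "N": "Neuro"}.get(first, "Other")


def load_withdrawn_reference() -> pd.DataFrame:
    """Reference detection calls for the 18 market-withdrawn cardiotoxic
    drugs in the zebrafish and cardiomyocyte screens.

    Columns: compound, atc_code, subgroup, zebrafish_detected,
    hipsc_detected (0/1).
    """
    with resources.files("cardioscreen.data").joinpath(
        "withdrawn_calls.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["zebrafish_detected"] = df["zebrafish_detected"].astype(bool)
    df["hipsc_detected"] = df["hipsc_detected"].astype(bool)
    return df


def withdrawn_summary(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Withdrawn-drug sensitivity per model, overall and by ATC subgroup.

    Returns a table with columns model, subgroup, detected, total,
    sensitivity_pct and sensitivity_reported (integer percent, half-up).
    """
    df = load_withdrawn_reference() if reference is None else reference
    rows = []
    for model, col in (("zebrafish", "zebrafish_detected"),
                       ("hipsc", "hipsc_detected")):
        groups = [("All", df)] + [
            (g, sub) for g, sub in df.groupby("subgroup")
        ]
        for gname, sub in groups:
            calls = dict(zip(sub["compound"], sub[col]))
            sens = withdrawn_sensitivity(calls, set(sub["compound"]))
            rows.append({
                "model": model,
                "subgroup": gname,
                "detected": int(sub[col].sum()),
                "total": len(sub),
                "sensitivity_pct": sens,
                "sensitivity_reported": round_half_up(sens),
            })
    return pd.DataFrame(rows)
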