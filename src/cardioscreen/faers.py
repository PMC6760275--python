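"""Disproportionality analysis of spontaneous adverse-event reports.

Given a table of curated reports, each drug is scored against its major
cardiotoxicity event (MCE) — the term, among the 29 cardiotoxicity terms,
with the most reports mentioning the drug in any role.  The proportional
reporting ratio (PRR) compares the event's reporting rate in the drug's
report pool with its rate in 100 background pools of equal size drawn from
other drugs' reports; each background is chosen by a genetic algorithm that
matches the pools' covariate distributions (indication, co-medication,
gender, binned age, binned weight) to the drug's, mitigating confounding by
patient niche.  A drug is called positive when the mean PRR of its MCE is
2 or above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 29 cardiotoxicity terms used to pick each drug's MCE.
CARDIOTOX_TERMS = (
    "palpitations",
    "central venous catheterization",
    "ventricular fibrillation",
    "sudden cardiac death",
    "myocardial infarction",
    "dilated cardiomyopathy",
    "cardiomegaly",
    "prolonged QT interval",
    "left ventricular hypertrophy",
    "heart murmur",
    "sinus tachycardia",
    "ventricular tachycardia",
    "bradycardia",
    "mitral valve insufficiency",
    "aortic valve insufficiency",
    "tricuspid valve insufficiency",
    "atrial septal defects",
    "ventricular septal defects",
    "torsades de pointes",
    "tachyarrhythmia",
    "cardiac arrhythmia",
    "ejection fraction decreased",
    "cardiotoxicity",
    "right-sided heart failure",
    "cardiogenic shock",
    "coronary heart disease",
    "pericardial effusion",
    "heart diseases",
    "cardiovascular diseases",
)

PRR_POSITIVE_THRESHOLD = 2.0

_CONTENT_FIELDS = (
    "primary_suspect", "secondary_suspects", "concomitant", "events",
    "indication", "route", "gender", "age", "weight", "outcome",
    "event_date",
)


def curate(
    reports: pd.DataFrame,
    dedup_window_days: int = 7,
    age_range: tuple[float, float] = (0.0, 120.0),
    weight_range: tuple[float, float] = (1.0, 300.0),
) -> tuple[pd.DataFrame, dict]:
    """Deduplicate and validate a raw report table.

    Reports with identical content in every field but deposited within
    ``dedup_window_days`` of each other collapse to the earliest deposit.
    Rows with out-of-range age or weight, or unparseable dates, are dropped.
    Returns the curated table and a log of dropped/collapsed counts.
    """
    df = reports.copy()
    n0 = len(df)
    age = pd.to_numeric(df["age"], errors="coerce")
    weight = pd.to_numeric(df["weight"], errors="coerce")
    dep = pd.to_datetime(df["deposit_date"], errors="coerce")
    valid = (
        age.between(*age_range)
        & weight.between(*weight_range)
        & dep.notna()
        & pd.to_datetime(df["event_date"], errors="coerce").notna()
    )
    df = df[valid].copy()
    n_invalid = n0 - len(df)

    df["_deposit"] = pd.to_datetime(df["deposit_date"])
    df = df.sort_values("_deposit", kind="stable")
    keep = []
    n_dups = 0
    for _, grp in df.groupby(list(_CONTENT_FIELDS), sort=False):
        last_kept = None
        for idx, dt in zip(grp.index, grp["_deposit"]):
            if last_kept is None or (dt - last_kept).days > dedup_window_days:
                keep.append(idx)
                last_kept = dt
            else:
                n_dups += 1
    out = df.loc[sorted(keep)].drop(columns="_deposit")
    log = {"input_rows": n0, "dropped_invalid": n_invalid,
           "collapsed_duplicates": n_dups, "output_rows": len(out)}
    return out.reset_index(drop=True), log


def _mentions_drug(df: pd.DataFrame, drug: str) -> pd.Series:
    """Reports mentioning the drug in any role (primary, secondary,
    concomitant)."""
    def in_multi(col):
        return df[col].fillna("").str.split(";").apply(lambda xs: drug in xs)

    return (
        (df["primary_suspect"] == drug)
        | in_multi("secondary_suspects")
        | in_multi("concomitant")
    )


def _has_event(df: pd.DataFrame, event: str) -> pd.Series:
    return df["events"].fillna("").str.split(";").apply(lambda xs: event in xs)


def mce(drug: str, reports: pd.DataFrame,
        terms: tuple[str, ...] = CARDIOTOX_TERMS) -> str:
    """The drug's major cardiotoxicity event: the term with most reports.

    Reports count irrespective of the drug's role; ties break by the fixed
    vocabulary order.
    """
    mask = _mentions_drug(reports, drug)
    if not mask.any():
        raise ValueError(f"drug {drug!r} appears in no report")
    sub = reports[mask]
    counts = {t: int(_has_event(sub, t).sum()) for t in terms}
    return max(terms, key=lambda t: counts[t])  # max is stable → first wins ties


# ---------------------------------------------------------------------------
# genetic-algorithm background matching
# ---------------------------------------------------------------------------


@dataclass
class GaParams:
    """Hyperparameters of the background-matching genetic algorithm."""

    population: int = 50
    generations: int = 100
    mutation_rate: float = 0.05
    tournament: int = 3
    elite: int = 2


@dataclass
class _Attrs:
    """Integer-coded report attributes for fast distribution distances."""

    codes: list[np.ndarray]  # categorical code per report, one per attribute
    sizes: list[int]
    conco: np.ndarray  # reports x drugs count matrix
    field_names: tuple[str, ...] = (
        "indication", "gender", "age_bin", "weight_bin"
    )


def _encode_attrs(df: pd.DataFrame, drugs: list[str]) -> _Attrs:
    codes, sizes = [], []
    for col, binned in (("indication", False), ("gender", False),
                        ("age", True), ("weight", True)):
        if binned:
            v = pd.to_numeric(df[col], errors="coerce").to_numpy()
            edges = np.quantile(v[np.isfinite(v)], np.linspace(0, 1, 9)[1:-1])
            code = np.searchsorted(edges, v)
            n = len(edges) + 1
        else:
            cat = pd.Categorical(df[col].astype(str))
            code = cat.codes.astype(np.int64)
            n = len(cat.categories)
        codes.append(code.astype(np.int64))
        sizes.append(n)
    drug_idx = {d: i for i, d in enumerate(drugs)}
    conco = np.zeros((len(df), len(drugs)), dtype=np.float64)
    for r, s in enumerate(df["concomitant"].fillna("")):
        for d in s.split(";"):
            if d in drug_idx:
                conco[r, drug_idx[d]] += 1
    return _Attrs(codes=codes, sizes=sizes, conco=conco)


def _target_dists(attrs: _Attrs, idx: np.ndarray):
    cats = [
        np.bincount(c[idx], minlength=n) / len(idx)
        for c, n in zip(attrs.codes, attrs.sizes)
    ]
    tot = attrs.conco[idx].sum()
    conco = attrs.conco[idx].sum(axis=0) / tot if tot > 0 else None
    return cats, conco


def attribute_distance(attrs: _Attrs, pool: np.ndarray, target) -> float:
    """Summed total-variation distance between a pool's attribute
    distributions and the target distributions."""
    return float(-_fitness_batch(attrs, np.asarray(pool)[None, :], target)[0])


def _fitness_batch(attrs: _Attrs, pools: np.ndarray, target) -> np.ndarray:
    """Fitness (= minus summed TV distance) of many pools at once.

    ``pools`` is a (k, m) integer array of report indices.
    """
    cats_t, conco_t = target
    k, m = pools.shape
    total = np.zeros(k)
    offsets = np.arange(k)[:, None]
    for c, n, ct in zip(attrs.codes, attrs.sizes, cats_t):
        flat = c[pools] + offsets * n
        counts = np.bincount(flat.ravel(), minlength=k * n).reshape(k, n)
        total += 0.5 * np.abs(counts / m - ct).sum(axis=1)
    if conco_t is not None:
        sums = attrs.conco[pools].sum(axis=1)  # (k, n_drugs)
        tots = sums.sum(axis=1, keepdims=True)
        ok = tots[:, 0] > 0
        dist = np.divide(sums, tots, out=np.zeros_like(sums), where=tots > 0)
        total += np.where(ok, 0.5 * np.abs(dist - conco_t).sum(axis=1), 1.0)
    return -total


def select_backgrounds(
    drug: str,
    reports: pd.DataFrame,
    n_pools: int = 100,
    ga: GaParams | None = None,
    seed: int = 0,
    drugs: list[str] | None = None,
) -> list[np.ndarray]:
    """Select matched background report pools with a genetic algorithm.

    Each pool has the same number of reports as the drug's pool and draws
    only from reports not mentioning the drug.  Candidate pools evolve by
    tournament selection, uniform membership crossover (repaired to pool
    size) and swap mutation, with elitism, maximising minus the summed
    total-variation distance of the attribute distributions (indication,
    co-medication, gender, binned age, binned weight) from the drug pool's.
    Fully seeded and reproducible.
    """
    ga = ga or GaParams()
    rng = np.random.default_rng(seed)
    mask = _mentions_drug(reports, drug).to_numpy()
    drug_idx = np.flatnonzero(mask)
    bg_idx = np.flatnonzero(~mask)
    m = len(drug_idx)
    if m == 0:
        raise ValueError(f"drug {drug!r} appears in no report")
    if len(bg_idx) < m:
        raise ValueError("background smaller than the drug's pool")

    if drugs is None:
        drugs = sorted(set(reports["primary_suspect"]) - {drug})
    attrs = _encode_attrs(reports, drugs)
    target = _target_dists(attrs, drug_idx)

    pools = []
    for _ in range(n_pools):
        pop = np.stack([
            rng.choice(bg_idx, size=m, replace=False)
            for _ in range(ga.population)
        ])
        fitness = _fitness_batch(attrs, pop, target)
        for _gen in range(ga.generations):
            order = np.argsort(fitness)[::-1]
            children = []
            while len(children) < ga.population - ga.elite:
                # tournament selection of two parents
                parents = []
                for _ in range(2):
                    cand = rng.integers(0, ga.population, ga.tournament)
                    parents.append(pop[cand[np.argmax(fitness[cand])]])
                # uniform crossover on the union, repaired to size m
                union = np.union1d(parents[0], parents[1])
                child = rng.choice(union, size=m, replace=False)
                # swap mutation: replace members with random outsiders
                n_mut = rng.binomial(m, ga.mutation_rate)
                if n_mut:
                    pos = rng.choice(m, size=n_mut, replace=False)
                    child[pos] = rng.choice(bg_idx, size=n_mut, replace=False)
                    child = np.unique(child)
                    while len(child) < m:
                        extra = rng.choice(bg_idx, size=m - len(child))
                        child = np.unique(np.concatenate([child, extra]))
                children.append(child)
            children = np.stack(children)
            child_fit = _fitness_batch(attrs, children, target)
            pop = np.concatenate([pop[order[: ga.elite]], children])
            fitness = np.concatenate([fitness[order[: ga.elite]], child_fit])
        pools.append(pop[int(np.argmax(fitness))])
    return pools


def prr(
    drug_reports: pd.DataFrame,
    background: pd.DataFrame,
    event: str,
) -> float:
    """Proportional reporting ratio of an event for one drug vs one pool.

    With a = drug reports carrying the event, b = those without, and c, d
    their analogues in the background pool: PRR = [a/(a+b)] / [c/(c+d)].
    When the event is absent from the background (c = 0) the Haldane
    correction adds 0.5 to all four cells.
    """
    if len(drug_reports) == 0:
        raise ValueError("drug pool is empty")
    a = int(_has_event(drug_reports, event).sum())
    b = len(drug_reports) - a
    c = int(_has_event(background, event).sum())
    d = len(background) - c
    if c == 0:
        a, b, c, d = a + 0.5, b + 0.5, 0.5, d + 0.5
    return float((a / (a + b)) / (c / (c + d)))


@dataclass
class Association:
    """A drug's MCE with its averaged PRR over matched backgrounds."""

    drug: str
    event: str
    pool_prrs: list[float] = field(repr=False, default_factory=list)

    @property
    def mean_prr(self) -> float:
        return float(np.mean(self.pool_prrs))

    @property
    def positive(self) -> bool:
        return self.mean_prr >= PRR_POSITIVE_THRESHOLD


def drug_event_prr(
    drug: str,
    reports: pd.DataFrame,
    event: str,
    n_pools: int = 100,
    ga: GaParams | None = None,
    seed: int = 0,
) -> Association:
    """Averaged PRR of one drug-event pair over matched background pools."""
    pools = select_backgrounds(drug, reports, n_pools=n_pools, ga=ga, seed=seed)
    drug_pool = reports[_mentions_drug(reports, drug)]
    prrs = [prr(drug_pool, reports.iloc[p], event) for p in pools]
    return Association(drug=drug, event=event, pool_prrs=prrs)


def classify_faers(
    drug: str,
    reports: pd.DataFrame,
    n_pools: int = 100,
    ga: GaParams | None = None,
    seed: int = 0,
    positive_allowlist: set[str] = frozenset(),
) -> tuple[bool, Association]:
    """Positive/negative cardiotoxicity call for a drug from its reports.

    The drug's MCE is selected among the 29 cardiotoxicity terms; the drug
    is positive when the MCE's mean PRR is 2 or above.  Drugs on the
    explicit curation allowlist are positive regardless (the documented
    override for well-established cardiotoxicants).
    """
    event = mce(drug, reports)
    assoc = drug_event_prr(drug, reports, event, n_pools=n_pools, ga=ga,
                           seed=seed)
    positive = assoc.positive or drug in positive_allowlist
    return positive, assoc
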