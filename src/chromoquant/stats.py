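"""Group summaries, unpaired t-tests and Arc-positive prevalence.

Two summary conventions coexist, both used in the source experiments:
per-nucleus comparisons (each data point is one nucleus; SEM across nuclei)
for puncta counts and areas, and per-experiment fractions (each data point
is one culture/experiment; SEM across experiments) for Arc-positive
prevalence.

The default test is Student's pooled-variance unpaired t-test; Welch's
correction is available via a flag.  Significance stars follow the usual
figure convention (ns, *, **, ***, **** at 0.05 / 0.01 / 0.001 / 0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .nuclei import NucleusMeasurement

__all__ = [
    "GroupComparison",
    "group_summary",
    "unpaired_t_test",
    "p_to_stars",
    "arc_positive_fraction",
]


@dataclass(frozen=True)
class GroupComparison:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t: float
    df: float
    p_value: float
    stars: str
    welch: bool

    def summary(self) -> str:
        lines = [
            f"{self.name_a}: {self.mean_a:.3g} +/- {self.sem_a:.2g} (n={self.n_a})",
            f"{self.name_b}: {self.mean_b:.3g} +/- {self.sem_b:.2g} (n={self.n_b})",
            f"{'Welch' if self.welch else 'Student'} unpaired t test: "
            f"t({self.df:.4g}) = {self.t:.4g}, p = {self.p_value:.3g} [{self.stars}]",
        ]
        return "\n".join(lines)


def group_summary(values: Sequence[float]) -> tuple[int, float, float]:
    """(n, mean, SEM) with sample SD (n-1 denominator); requires n >= 2."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values for a group summary")
    return int(v.size), float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def p_to_stars(p: float) -> str:
    """Figure-convention significance stars; total over p in [0, 1]."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def unpaired_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = False,
    name_a: str = "A",
    name_b: str = "B",
) -> GroupComparison:
    """Two-sided unpaired t-test (Student by default, Welch by flag)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    df = float(res.df)
    na, ma, sa = group_summary(a)
    nb, mb, sb = group_summary(b)
    return GroupComparison(
        name_a=name_a,
        name_b=name_b,
        n_a=na,
        n_b=nb,
        mean_a=ma,
        mean_b=mb,
        sem_a=sa,
        sem_b=sb,
        t=t,
        df=df,
        p_value=p,
        stars=p_to_stars(p),
        welch=welch,
    )


def arc_positive_fraction(
    measurements: Iterable[NucleusMeasurement],
) -> tuple[float, float | None, int]:
    """Arc-positive prevalence: mean +/- SEM of per-experiment fractions.

    Each experiment contributes one fraction (positives / classified nuclei);
    the return value is ``(mean fraction, SEM across experiments, n
    experiments)``.  SEM is None with a single experiment.
    """
    per_exp: dict[str, list[str]] = {}
    for m in measurements:
        if m.arc_class is None:
            continue
        per_exp.setdefault(m.experiment_id, []).append(m.arc_class)
    if not per_exp:
        raise ValueError("no classified nuclei")
    fractions = np.array(
        [np.mean([c == "positive" for c in classes]) for classes in per_exp.values()]
    )
    n = len(fractions)
    mean = float(fractions.mean())
    sem = float(fractions.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return mean, sem, n
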