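"""Recombination-assay quantification: replicate frequencies and Welch tests.

In vivo excision/insertion assays score, per biological replicate, how many
of a fixed number of picked colonies (30 by convention) carry the
event-specific PCR band. The analysis unit is the per-replicate proportion
k/n; frequencies are reported as mean ± sample SD over replicates, and
constructs are compared with pairwise Welch's t-tests (unequal variances,
two-sided), summarized as compact letter groupings: constructs sharing a
letter are not significantly different at the chosen alpha.

Welch's statistic for samples a, b:

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)

with the Welch-Satterthwaite degrees of freedom. The zero-variance corner
(e.g. two saturated 100% constructs) is undefined under the test and is
resolved explicitly: equal means give t = 0, p = 1; unequal means are
flagged degenerate and reported p = 0 with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger("integronkit")

EVENT_TYPES = ("excision", "insertion_5p", "insertion_3p")


@dataclass(frozen=True)
class AssayReplicate:
    """One biological replicate of a colony-PCR recombination assay."""

    construct_id: str
    event_type: str
    n_colonies: int
    k_positive: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type: {self.event_type!r}")
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if not 0 <= self.k_positive <= self.n_colonies:
            raise ValueError("k_positive must be in [0, n_colonies]")

    @property
    def fraction(self) -> float:
        return self.k_positive / self.n_colonies


@dataclass(frozen=True)
class FrequencyEstimate:
    """Mean ± sample SD (n-1 denominator) of per-replicate event frequencies."""

    mean: float
    sd: float
    n_replicates: int


def estimate_frequency(replicates: Sequence[AssayReplicate]) -> FrequencyEstimate:
    """Mean and sample SD of per-replicate proportions for one construct/event."""
    if len(replicates) < 2:
        raise ValueError("estimate_frequency needs at least 2 replicates")
    constructs = {r.construct_id for r in replicates}
    events = {r.event_type for r in replicates}
    if len(constructs) > 1 or len(events) > 1:
        raise ValueError(
            f"replicates mix constructs/events: {sorted(constructs)} / {sorted(events)}"
        )
    fracs = np.array([r.fraction for r in replicates])
    return FrequencyEstimate(
        mean=float(fracs.mean()),
        sd=float(fracs.std(ddof=1)),
        n_replicates=len(replicates),
    )


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sided Welch's t-test on two samples of per-replicate fractions."""
    xa, xb = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(xa), len(xb)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    diff = xa.mean() - xb.mean()
    if va == 0 and vb == 0:
        if diff == 0:
            return WelchResult(t=0.0, df=float(na + nb - 2), p=1.0)
        logger.warning(
            "Welch's test degenerate: both samples zero-variance with unequal "
            "means; reporting p = 0"
        )
        return WelchResult(
            t=math.copysign(math.inf, diff), df=float(na + nb - 2), p=0.0,
            degenerate=True,
        )
    se2 = va / na + vb / nb
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return WelchResult(t=float(t), df=float(df), p=float(p))


def pairwise_welch(
    samples: dict[str, Sequence[float]],
    *,
    correction: Optional[str] = None,
) -> "pd.DataFrame":
    """Symmetric matrix of pairwise Welch p-values.

    ``correction="holm"`` applies Holm's step-down adjustment across the
    upper triangle (no correction by default).
    """
    import pandas as pd

    names = list(samples)
    n = len(names)
    mat = np.ones((n, n))
    pairs, raw = [], []
    for i in range(n):
        for j in range(i + 1, n):
            res = welch_t_test(samples[names[i]], samples[names[j]])
            pairs.append((i, j))
            raw.append(res.p)
    if correction == "holm" and raw:
        from statsmodels.stats.multitest import multipletests

        raw = list(multipletests(raw, method="holm")[1])
    elif correction not in (None, "holm"):
        raise ValueError(f"unknown correction: {correction!r}")
    for (i, j), p in zip(pairs, raw):
        mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=names, columns=names)


def group_letters(pairwise_p, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from a symmetric p-value matrix.

    Greedy clique cover in construct order: each construct joins every
    existing letter group with which it has no significant difference
    (all pairwise p >= alpha against current members); if none accepts it,
    it opens a new letter. Constructs sharing a letter are therefore never
    significantly different. Deterministic under the given construct order.
    """
    import pandas as pd

    if isinstance(pairwise_p, pd.DataFrame):
        names = list(pairwise_p.index)
        mat = pairwise_p.to_numpy()
    else:
        mat = np.asarray(pairwise_p, float)
        names = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("pairwise_p must be a symmetric square matrix")
    groups: list[list[int]] = []
    for idx in range(len(names)):
        placed = False
        for members in groups:
            if all(mat[idx, m] >= alpha for m in members):
                members.append(idx)
                placed = True
        if not placed:
            # open a new letter and absorb earlier constructs compatible with it
            fresh = [idx]
            for earlier in range(idx):
                if all(mat[earlier, m] >= alpha for m in fresh):
                    fresh.append(earlier)
            groups.append(sorted(fresh))
    letters = {name: "" for name in names}
    for g, members in enumerate(groups):
        letter = chr(ord("a") + g)
        for m in members:
            letters[names[m]] += letter
    return letters


def read_assay_csv(path) -> list[AssayReplicate]:
    """CSV columns: construct_id, event_type, replicate, n_colonies, k_positive."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"construct_id", "event_type", "n_colonies", "k_positive"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"assay CSV missing columns: {sorted(missing)}")
    return [
        AssayReplicate(
            str(row.construct_id), str(row.event_type),
            int(row.n_colonies), int(row.k_positive),
        )
        for row in frame.itertuples()
    ]


def summarize_assay(
    replicates: Iterable[AssayReplicate],
    *,
    alpha: float = 0.05,
    correction: Optional[str] = None,
) -> "pd.DataFrame":
    """Per-(construct, event) frequency table with significance letter groups.

    Letter groups are computed within each event type across constructs.
    """
    import pandas as pd

    by_key: dict[tuple[str, str], list[AssayReplicate]] = {}
    for r in replicates:
        by_key.setdefault((r.construct_id, r.event_type), []).append(r)
    rows = []
    for event in sorted({k[1] for k in by_key}):
        samples = {
            construct: [r.fraction for r in reps]
            for (construct, ev), reps in by_key.items()
            if ev == event
        }
        letters = (
            group_letters(pairwise_welch(samples, correction=correction), alpha)
            if len(samples) > 1
            else {c: "a" for c in samples}
        )
        for (construct, ev), reps in by_key.items():
            if ev != event:
                continue
            est = estimate_frequency(reps)
            rows.append(
                {
                    "construct": construct,
                    "event": event,
                    "mean": est.mean,
                    "sd": est.sd,
                    "n": est.n_replicates,
                    "letter_group": letters[construct],
                }
            )
    return pd.DataFrame(rows).sort_values(["event", "construct"]).reset_index(drop=True)
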