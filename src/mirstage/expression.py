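"""Count normalisation, fold changes, and the two-library exact test.

Expression is normalised to transcripts per million clean reads (NE), with
a 0.01 TPM floor so zero counts yield finite log2 fold changes.  Differences
between two libraries without replicates are scored with the Audic-Claverie
statistic: given a count x in library 1 (total N1), the probability of
observing y in library 2 (total N2) is

    p(y|x) = (N2/N1)^y * (x+y)! / ( x! y! (1+N2/N1)^(x+y+1) )

whose lower/upper cumulative tails give a two-sided p-value.  The DE class
(up / down / equal) follows the NE ratio alone (>2, <=1/2, otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import gammaln

NE_FLOOR = 0.01


@dataclass(frozen=True)
class CountPair:
    """Counts of one miRNA in two libraries with their clean-read totals."""

    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValueError("negative count")
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("library totals must be positive")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("count exceeds library total")

    def swapped(self) -> "CountPair":
        return CountPair(self.y, self.x, self.N2, self.N1)


def normalize(count: int, clean_total: int, floor: float = NE_FLOOR) -> float:
    """Normalized expression in TPM, floored at 0.01 for zero/low counts."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    ne = count / clean_total * 1e6
    return ne if ne >= floor else floor


def log2_fold_change(pair: CountPair, floor: float = NE_FLOOR) -> float:
    """log2(NE_B / NE_A) on floored normalized expression."""
    return math.log2(
        normalize(pair.y, pair.N2, floor) / normalize(pair.x, pair.N1, floor)
    )


def _log_mass(x: int, y, ratio: float) -> np.ndarray | float:
    y = np.asarray(y, dtype=float)
    lr = math.log(ratio)
    l1r = math.log1p(ratio)
    return (
        y * lr
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * l1r
    )


def ac_probability(pair: CountPair, y: int | None = None) -> float:
    """The exact mass p(y | x, N1, N2); defaults to the pair's own y.

    Evaluated through log-gamma so it stays finite for counts up to 1e7.
    """
    if y is None:
        y = pair.y
    if y < 0:
        raise ValueError("negative count")
    return float(np.exp(_log_mass(pair.x, y, pair.N2 / pair.N1)))


def _log_tail(x: int, y: int, ratio: float, upper: bool) -> float:
    """log of sum of masses k>=y (upper) or k<=y (lower), summed from y outward."""
    log_terms = [float(_log_mass(x, y, ratio))]
    k = y
    p_succ = ratio / (1.0 + ratio)  # mass(k+1)/mass(k) = (x+k+1)/(k+1) * p_succ
    mode = x * ratio
    while True:
        if upper:
            step = math.log((x + k + 1) / (k + 1) * p_succ)
            k += 1
        else:
            if k == 0:
                break
            step = -math.log((x + k) / k * p_succ)
            k -= 1
        log_terms.append(log_terms[-1] + step)
        past_mode = (k > mode) if upper else (k < mode)
        if past_mode and log_terms[-1] < log_terms[0] - 46 and len(log_terms) > 4:
            break
        if len(log_terms) > 10_000_000:  # pragma: no cover
            raise RuntimeError("tail summation failed to converge")
    m = max(log_terms)
    return m + math.log(sum(math.exp(t - m) for t in log_terms))


def ac_pvalue(pair: CountPair) -> float:
    """Two-sided Audic-Claverie p-value: min(1, 2*min(C, D)).

    C is the lower cumulative tail including the observed y, D = 1 - C the
    strict upper tail, so the two tails partition the mass exactly once.
    This makes the two-sided p exactly invariant under swapping the
    libraries and near-uniform under a Poisson null; combinations that
    count the observed point in both tails satisfy neither.  The shorter
    tail is accumulated directly in log space.
    """
    x, y = pair.x, pair.y
    ratio = pair.N2 / pair.N1
    mean = (x + 1) * ratio
    if y <= mean:
        C = math.exp(_log_tail(x, y, ratio, upper=False))
        D = 1.0 - C
    else:
        D = math.exp(_log_tail(x, y + 1, ratio, upper=True))
        C = 1.0 - D
    p = 2.0 * min(C, D)
    return min(1.0, max(p, 5e-324))


def classify_de(ne_a: float, ne_b: float) -> str:
    """DE class from the NE ratio: up if >2, down if <=1/2, else equal."""
    ratio = ne_b / ne_a
    if ratio > 2:
        return "up"
    if ratio <= 0.5:
        return "down"
    return "equal"


def de_table(
    counts: pd.DataFrame,
    totals: dict[str, int],
    lib_a: str,
    lib_b: str,
    floor: float = NE_FLOOR,
    p_max: float | None = None,
) -> pd.DataFrame:
    """Per-miRNA DE table comparing ``lib_b`` against ``lib_a``.

    ``counts`` holds one row per miRNA with one column per library.  When
    ``p_max`` is given, rows classified up/down must additionally reach that
    p-value; otherwise the class follows the NE ratio alone.
    """
    rows = []
    for name, row in counts.iterrows():
        x, y = int(row[lib_a]), int(row[lib_b])
        pair = CountPair(x, y, totals[lib_a], totals[lib_b])
        ne_a = normalize(x, totals[lib_a], floor)
        ne_b = normalize(y, totals[lib_b], floor)
        p = ac_pvalue(pair)
        cls = classify_de(ne_a, ne_b)
        if p_max is not None and cls != "equal" and p > p_max:
            cls = "equal"
        rows.append(
            {
                "miRNA": name,
                f"count_{lib_a}": x,
                f"count_{lib_b}": y,
                f"NE_{lib_a}": ne_a,
                f"NE_{lib_b}": ne_b,
                "log2fc": math.log2(ne_b / ne_a),
                "p_value": p,
                "de_class": cls,
            }
        )
    df = pd.DataFrame(rows).set_index("miRNA")
    df["log2fc_rounded"] = df["log2fc"].map(lambda v: round_half_up(v, 2))
    return df


def round_half_up(value: float, decimals: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    return float(
        Decimal(repr(value)).quantize(
            Decimal("1." + "0" * decimals), rounding=ROUND_HALF_UP
        )
    )


def expression_matrix(
    counts: pd.DataFrame, totals: dict[str, int], floor: float = NE_FLOOR
) -> pd.DataFrame:
    """NE (TPM, floored) per miRNA and library."""
    out = {}
    for lib in counts.columns:
        out[lib] = counts[lib].map(lambda c: normalize(int(c), totals[lib], floor))
    return pd.DataFrame(out, index=counts.index)


def cluster_prep(ne: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Heatmap-style data adjustment plus an average-linkage tree.

    Rows are log2-transformed, median-centred, and scaled to unit vector
    norm; the tree is average linkage on 1 - Pearson correlation distance.
    Rows that are constant after transformation get distance 0 to all rows.
    """
    if ne.shape[0] < 2 or ne.shape[1] < 2:
        raise ValueError("need at least 2 miRNAs and 2 conditions")
    m = np.log2(ne.to_numpy(dtype=float))
    m = m - np.median(m, axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(norms > 0, m / norms, 0.0)
    transformed = pd.DataFrame(m, index=ne.index, columns=ne.columns)
    centred = m - m.mean(axis=1, keepdims=True)
    sd = np.linalg.norm(centred, axis=1)
    n = m.shape[0]
    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                dist.append(0.0)
            else:
                r = float(centred[i] @ centred[j] / (sd[i] * sd[j]))
                dist.append(max(0.0, 1.0 - r))
    tree = linkage(np.array(dist), method="average")
    return transformed, tree


def top_n(ne: pd.DataFrame, library: str, n: int) -> pd.DataFrame:
    """The n most abundant miRNAs of one library (ties broken by name)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    order = sorted(ne.index, key=lambda name: (-ne.at[name, library], str(name)))
    return ne.loc[order].head(n)
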