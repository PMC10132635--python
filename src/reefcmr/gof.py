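"""Goodness-of-fit and overdispersion for capture-recapture data.

Capture histories are pooled to binary detected/not per primary period and
individuals are merged into groups of three (sparse monthly data leave the
classical contingency tests underpowered otherwise).  Four components are
computed, analogues of the classical transient/trap-dependence tests on
live-recapture data:

* ``test3_sr`` - are animals detected for the first time at occasion i
  re-detected later at the same rate as previously known animals?
* ``test3_sm`` - does the timing of the next re-detection differ between
  those two groups?
* ``test2_ct`` - among animals known before and re-detected after occasion
  i, is the next re-detection immediate (i+1) vs delayed equally often for
  animals detected vs not detected at i?
* ``test2_cl`` - among the delayed re-detections, does the timing of the
  next re-detection depend on detection at i?

Each component sums per-occasion Pearson chi-squares after merging table
columns with expected counts below 2 (degrees of freedom reduced
accordingly).  If any component rejects at level alpha, a variance-inflation
factor c-hat = sum(chi2)/sum(df) (floored at 1) rescales the likelihood in
QAIC-based model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .matrix import CaptureMatrix

COMPONENTS = ("test3_sr", "test3_sm", "test2_ct", "test2_cl")


@dataclass
class ComponentResult:
    name: str
    chi2: float
    df: int
    p: float  # NaN when df == 0 (insufficient data after pooling)


@dataclass
class GOFResult:
    components: dict[str, ComponentResult]
    chi2_total: float
    df_total: int
    dispersion: float   # raw sum(chi2)/sum(df), NaN if df_total == 0
    c_hat: float        # decision value: floored at 1; 1 unless a test fails
    failed: bool
    alpha: float = 0.05

    @property
    def use_qaic(self) -> bool:
        return self.failed


def pool_individuals(matrix: CaptureMatrix | np.ndarray,
                     group_size: int = 3) -> np.ndarray:
    """Merge individuals into groups with OR-ed primary-pooled histories.

    Individuals are sorted by first-detection primary, then identifier, and
    consecutive groups of ``group_size`` are combined by element-wise OR; a
    remainder smaller than ``group_size`` is merged into the final group.
    """
    if isinstance(matrix, CaptureMatrix):
        pooled = matrix.primary_pooled()
        ids = list(matrix.individuals)
    else:
        pooled = np.asarray(matrix, dtype=np.int8)
        ids = [f"{i:06d}" for i in range(pooled.shape[0])]
    n = pooled.shape[0]
    first = np.argmax(pooled == 1, axis=1)
    order = sorted(range(n), key=lambda i: (first[i], ids[i]))
    pooled = pooled[order]
    if n < group_size:
        warnings.warn(
            f"only {n} individuals; pooled into a single group", stacklevel=2)
        return (pooled.sum(axis=0, keepdims=True) > 0).astype(np.int8)
    n_groups = n // group_size
    groups = np.zeros((n_groups, pooled.shape[1]), dtype=np.int8)
    for g in range(n_groups):
        start = g * group_size
        end = start + group_size if g < n_groups - 1 else n
        groups[g] = (pooled[start:end].sum(axis=0) > 0).astype(np.int8)
    return groups


def build_marray(histories: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Release/next-re-detection summary of binary per-primary histories.

    Returns
    -------
    R : (T,) number detected (released) at each primary.
    m : (T, T) ``m[i, j]`` = number released at i next re-detected at j.
    """
    h = np.asarray(histories, dtype=np.int8)
    T = h.shape[1]
    R = h.sum(axis=0)
    m = np.zeros((T, T), dtype=int)
    for row in h:
        seen = np.nonzero(row)[0]
        for a, b in zip(seen[:-1], seen[1:]):
            m[a, b] += 1
    return R, m


def _merge_low_expected(table: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """Merge columns whose expected counts fall below ``threshold``.

    Zero-margin rows/columns are dropped first; then the column containing
    the smallest expected count is merged into its nearest neighbor until
    all expected counts reach the threshold or a single column remains.
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0] if t.size else t
    while t.size and t.shape[0] > 1 and t.shape[1] > 1:
        exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        if exp.min() >= threshold:
            break
        j = int(np.argmin(exp.min(axis=0)))
        k = j + 1 if j + 1 < t.shape[1] else j - 1
        t[:, k] += t[:, j]
        t = np.delete(t, j, axis=1)
    return t


def _pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square and df of a table after low-count pooling."""
    t = _merge_low_expected(table)
    if t.size == 0 or t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    chi2 = float(((t - exp) ** 2 / exp).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return chi2, df


def _next_detection(h: np.ndarray, i: int) -> np.ndarray:
    """Occasion of first detection after i per row; -1 if never again."""
    later = h[:, i + 1:]
    any_later = later.sum(axis=1) > 0
    nxt = np.where(any_later, np.argmax(later == 1, axis=1) + i + 1, -1)
    return nxt


def component_test(test_id: str, histories: np.ndarray) -> ComponentResult:
    """One goodness-of-fit component over pooled per-primary histories."""
    if test_id not in COMPONENTS:
        raise ValueError(f"unknown test {test_id!r}; choose from {COMPONENTS}")
    h = np.asarray(histories, dtype=np.int8)
    T = h.shape[1]
    if T < 3:
        return ComponentResult(test_id, 0.0, 0, float("nan"))
    first = np.argmax(h == 1, axis=1)
    chi2_sum, df_sum = 0.0, 0
    for i in range(1, T - 1):
        nxt = _next_detection(h, i)
        if test_id in ("test3_sr", "test3_sm"):
            at_i = h[:, i] == 1
            new = at_i & (first == i)
            old = at_i & (first < i)
            if test_id == "test3_sr":
                table = np.array([
                    [np.sum(new & (nxt > 0)), np.sum(new & (nxt < 0))],
                    [np.sum(old & (nxt > 0)), np.sum(old & (nxt < 0))],
                ])
            else:
                cols = range(i + 1, T)
                table = np.array([
                    [np.sum(new & (nxt == j)) for j in cols],
                    [np.sum(old & (nxt == j)) for j in cols],
                ])
        else:
            known = first < i          # present before i
            seen_after = nxt > 0
            det = known & (h[:, i] == 1) & seen_after
            und = known & (h[:, i] == 0) & seen_after
            if test_id == "test2_ct":
                table = np.array([
                    [np.sum(det & (nxt == i + 1)), np.sum(det & (nxt > i + 1))],
                    [np.sum(und & (nxt == i + 1)), np.sum(und & (nxt > i + 1))],
                ])
            else:
                cols = range(i + 2, T)
                table = np.array([
                    [np.sum(det & (nxt == j)) for j in cols],
                    [np.sum(und & (nxt == j)) for j in cols],
                ]).reshape(2, -1)
        c, d = _pearson_chi2(table)
        chi2_sum += c
        df_sum += d
    p = float(_chi2_dist.sf(chi2_sum, df_sum)) if df_sum > 0 else float("nan")
    return ComponentResult(test_id, chi2_sum, df_sum, p)


def chat_and_decision(components: dict[str, ComponentResult],
                      alpha: float = 0.05) -> GOFResult:
    """Combine component tests into the overdispersion decision.

    The fit "fails" if any component rejects at ``alpha``; only then is
    c-hat = sum(chi2)/sum(df) (floored at 1) used, switching model selection
    from AIC to QAIC.
    """
    chi2_total = sum(c.chi2 for c in components.values())
    df_total = sum(c.df for c in components.values())
    failed = any((c.p < alpha) for c in components.values()
                 if np.isfinite(c.p))
    if df_total == 0:
        warnings.warn("no usable degrees of freedom; c_hat defaults to 1",
                      stacklevel=2)
        dispersion = float("nan")
        c_hat = 1.0
    else:
        dispersion = chi2_total / df_total
        c_hat = max(1.0, dispersion) if failed else 1.0
    return GOFResult(components=dict(components), chi2_total=chi2_total,
                     df_total=df_total, dispersion=dispersion,
                     c_hat=c_hat, failed=failed, alpha=alpha)


def gof_summary(matrix: CaptureMatrix | np.ndarray, group_size: int = 3,
                alpha: float = 0.05) -> GOFResult:
    """Full pipeline: pool individuals, run all four components, decide."""
    groups = pool_individuals(matrix, group_size=group_size)
    comps = {t: component_test(t, groups) for t in COMPONENTS}
    return chat_and_decision(comps, alpha=alpha)
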