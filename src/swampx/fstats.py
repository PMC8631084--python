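"""f2/f3/f4 statistics with weighted block jackknife and the A-vs-X contrast.

All statistics are moments of population allele frequencies.  With sample
frequencies p̂ estimated from n called copies, the per-site estimators are

    f2(A, B)       = (p̂A − p̂B)² − ĥA/nA − ĥB/nB
    f3(A, B; C)    = (p̂C − p̂A)(p̂C − p̂B) − ĥC/nC      (C the outgroup)
    f4(A, B; C, D) = (p̂A − p̂B)(p̂C − p̂D)

where ĥ = p̂(1 − p̂)·n/(n − 1) is the unbiased heterozygosity; the ĥ/n terms
remove finite-sample bias, and f4 needs no correction.  Pooled estimates are
the global mean of per-site values; standard errors come from a weighted
delete-one block jackknife over contiguous genomic windows (blocks weighted
by their SNV counts), and Z = estimate / SE measures deviation from
treeness: under a clean tree separating {A, B} from {C, D}, f4 is zero in
expectation, gene flow between B and C drives it negative, and between B
and D positive (outgroup fixed as A).

The autosome-versus-X contrast compares the per-block f4 distributions of
the two chromosome classes with Welch's t-test: under male-biased gene flow
the X retains more of the recipient's original ancestry, so f4 on the X sits
further from zero than on the autosomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_data import AlleleCountTable, BlockPartition

__all__ = [
    "FStatConfig", "FStatResult", "ContrastResult", "JackknifeResult",
    "per_site_f2", "per_site_f3_outgroup", "per_site_f4", "block_jackknife",
    "f_statistic", "enumerate_f4", "f4_configurations", "f4_scan",
    "welch_t", "contrast_autosome_x", "compare_f3",
]


class FStatError(ValueError):
    pass


@dataclass(frozen=True)
class FStatConfig:
    """An f-statistic configuration: f2(A,B), f3(A,B;C) or f4(A,B;C,D)."""

    kind: str                       # f2 | f3_outgroup | f4
    populations: tuple[str, ...]
    bias_correction: bool = True

    def __post_init__(self) -> None:
        n_expected = {"f2": 2, "f3_outgroup": 3, "f4": 4}
        if self.kind not in n_expected:
            raise FStatError(f"unknown statistic kind {self.kind!r}")
        if len(self.populations) != n_expected[self.kind]:
            raise FStatError(
                f"{self.kind} needs {n_expected[self.kind]} populations, "
                f"got {self.populations}")
        if len(set(self.populations)) != len(self.populations):
            raise FStatError(f"repeated population in {self.populations}")

    def __str__(self) -> str:
        p = self.populations
        if self.kind == "f2":
            return f"f2({p[0]},{p[1]})"
        if self.kind == "f3_outgroup":
            return f"f3({p[0]},{p[1]};{p[2]})"
        return f"f4({p[0]},{p[1]};{p[2]},{p[3]})"


@dataclass
class JackknifeResult:
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    per_block: pd.DataFrame        # block_id, value (block mean), weight
    zero_se: bool = False


@dataclass
class FStatResult:
    config: FStatConfig
    estimate: float
    se: float
    z: float
    n_sites: int
    n_blocks: int
    per_block: pd.DataFrame
    n_skipped: int = 0
    zero_se: bool = False

    @property
    def p_value(self) -> float:
        """Two-sided normal p-value of the deviation from zero."""
        if self.zero_se:
            return float("nan")
        return 2.0 * sps.norm.sf(abs(self.z))


@dataclass
class ContrastResult:
    config: FStatConfig
    autosome: FStatResult
    x: FStatResult
    t_welch: float
    df_welch: float
    p_value: float
    direction: str                 # x_more_negative | x_less_negative | none


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def _freq(derived: np.ndarray, total: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, derived / np.maximum(total, 1), np.nan)


def _het(derived: np.ndarray, total: np.ndarray) -> np.ndarray:
    """Unbiased heterozygosity p̂(1−p̂)·n/(n−1); NaN where n < 2."""
    p = _freq(derived, total)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total >= 2, p * (1 - p) * total / np.maximum(total - 1, 1),
                        np.nan)


def per_site_f2(countsA: tuple[np.ndarray, np.ndarray],
                countsB: tuple[np.ndarray, np.ndarray],
                bias_correction: bool = True) -> np.ndarray:
    """Per-site f2 values; NaN marks sites skipped (uncallable correction)."""
    dA, tA = countsA
    dB, tB = countsB
    pA, pB = _freq(dA, tA), _freq(dB, tB)
    raw = (pA - pB) ** 2
    if not bias_correction:
        return raw
    return raw - _het(dA, tA) / tA - _het(dB, tB) / tB


def per_site_f3_outgroup(countsA, countsB, countsC,
                         bias_correction: bool = True) -> np.ndarray:
    """Per-site outgroup f3(A, B; C): shared drift of A and B seen from C."""
    dA, tA = countsA
    dB, tB = countsB
    dC, tC = countsC
    pA, pB, pC = _freq(dA, tA), _freq(dB, tB), _freq(dC, tC)
    raw = (pC - pA) * (pC - pB)
    if not bias_correction:
        return raw
    return raw - _het(dC, tC) / tC


def per_site_f4(countsA, countsB, countsC, countsD) -> np.ndarray:
    """Per-site f4(A, B; C, D) = (p̂A − p̂B)(p̂C − p̂D); no correction needed."""
    pA = _freq(*countsA)
    pB = _freq(*countsB)
    pC = _freq(*countsC)
    pD = _freq(*countsD)
    return (pA - pB) * (pC - pD)


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def block_jackknife(values: np.ndarray, block_ids: np.ndarray,
                    n_blocks: int | None = None) -> JackknifeResult:
    """Weighted delete-one-block jackknife of a mean of per-site values.

    NaN values mark skipped sites and are dropped together with sites whose
    block id is negative.  Block weights are site counts; the variance uses
    the weighted-pseudovalue form (h_j = n/m_j):

        τ_j = h_j·θ̂ − (h_j − 1)·θ_{−j}
        θ_J = g·θ̂ − Σ_j (1 − m_j/n)·θ_{−j}
        σ²  = (1/g) Σ_j (τ_j − θ_J)² / (h_j − 1)

    which reduces to the textbook delete-one jackknife when blocks are equal.
    """
    values = np.asarray(values, dtype=float)
    block_ids = np.asarray(block_ids)
    keep = block_ids >= 0
    vals = values[keep]
    ids = block_ids[keep]
    finite = np.isfinite(vals)
    if np.isinf(vals).any():
        bad = np.flatnonzero(keep)[np.isinf(vals[:])][:1]
        raise FStatError(f"non-finite per-site value at site index {bad}")
    vals, ids = vals[finite], ids[finite]
    if vals.size == 0:
        raise FStatError("no usable sites for jackknife")
    n_blocks = n_blocks or int(ids.max()) + 1
    m = np.bincount(ids, minlength=n_blocks).astype(float)
    s = np.bincount(ids, weights=vals, minlength=n_blocks)
    nonempty = m > 0
    m, s = m[nonempty], s[nonempty]
    labels = np.flatnonzero(nonempty)
    g = m.size
    if g < 2:
        raise FStatError("jackknife needs at least 2 non-empty blocks")
    n = m.sum()
    total = s.sum()
    theta = total / n
    theta_del = (total - s) / (n - m)          # delete-one-block estimates
    h = n / m
    tau = h * theta - (h - 1.0) * theta_del    # weighted pseudovalues
    theta_jack = g * theta - ((1.0 - m / n) * theta_del).sum()
    if np.all(vals == vals[0]):   # constant input: SE exactly 0, flagged
        var = 0.0
    else:
        var = ((tau - theta_jack) ** 2 / (h - 1.0)).sum() / g
    se = math.sqrt(max(var, 0.0))
    zero_se = se == 0.0
    if zero_se:
        z = math.copysign(math.inf, theta) if theta != 0 else 0.0
    else:
        z = theta / se
    per_block = pd.DataFrame({"block_id": labels, "value": s / m, "weight": m})
    return JackknifeResult(float(theta), float(se), float(z), int(n), int(g),
                           per_block, zero_se)


# ---------------------------------------------------------------------------
# pooled statistics
# ---------------------------------------------------------------------------

def _per_site_values(table: AlleleCountTable,
                     config: FStatConfig) -> np.ndarray:
    cts = [table.counts(p) for p in config.populations]
    if config.kind == "f2":
        return per_site_f2(cts[0], cts[1], config.bias_correction)
    if config.kind == "f3_outgroup":
        return per_site_f3_outgroup(cts[0], cts[1], cts[2],
                                    config.bias_correction)
    return per_site_f4(*cts)


def f_statistic(table: AlleleCountTable, config: FStatConfig,
                partition: BlockPartition) -> FStatResult:
    """Pooled f-statistic with jackknife SE and per-block detail."""
    values = _per_site_values(table, config)
    if np.isinf(values).any():
        i = int(np.flatnonzero(np.isinf(values))[0])
        site = table.sites.iloc[i]
        raise FStatError(
            f"non-finite per-site value at {site.chrom}:{site.pos}")
    jk = block_jackknife(values, partition.block_ids, partition.n_blocks)
    usable = (partition.block_ids >= 0) & np.isfinite(values)
    n_skipped = int(((partition.block_ids >= 0) & ~np.isfinite(values)).sum())
    assert int(usable.sum()) == jk.n_sites
    return FStatResult(config, jk.estimate, jk.se, jk.z, jk.n_sites,
                       jk.n_blocks, jk.per_block, n_skipped, jk.zero_se)


def f4_configurations(populations: Sequence[str],
                      outgroup: str) -> list[tuple[str, str, str]]:
    """All unordered triples {B, C, D} for f4(outgroup, B; C, D) tests."""
    others = sorted(p for p in populations if p != outgroup)
    if outgroup not in populations:
        raise FStatError(f"outgroup {outgroup!r} not among populations")
    return list(itertools.combinations(others, 3))


def enumerate_f4(table: AlleleCountTable, outgroup: str,
                 partition: BlockPartition, alpha: float = 0.05,
                 correction: str = "bonferroni") -> pd.DataFrame:
    """f4(outgroup, B; C, D) over every unordered triple of populations.

    Per triple, the three possible topologies are tested and the
    best-fitting one (smallest |Z|, ties broken lexicographically) is
    reported as the tree hypothesis; its deviation from zero is tested with
    Bonferroni control across the enumeration.
    """
    if correction != "bonferroni":
        raise FStatError("only Bonferroni correction is supported")
    triples = f4_configurations(table.populations, outgroup)
    rows = []
    for triple in triples:
        x, y, z_ = triple
        orientations = [(x, y, z_), (y, x, z_), (z_, x, y)]
        results = []
        for b, c, d in orientations:
            cfg = FStatConfig("f4", (outgroup, b, c, d))
            results.append(f_statistic(table, cfg, partition))
        best = min(range(3), key=lambda i: (abs(results[i].z),
                                            orientations[i]))
        r = results[best]
        rows.append({
            "B": orientations[best][0], "C": orientations[best][1],
            "D": orientations[best][2], "config": str(r.config),
            "estimate": r.estimate, "se": r.se, "z": r.z,
            "p": r.p_value, "n_sites": r.n_sites, "n_blocks": r.n_blocks,
        })
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * n_tests, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def f4_scan(table: AlleleCountTable, config: FStatConfig, chrom: str,
            window: int | None = None) -> pd.DataFrame:
    """Per-site (or per-window mean) f4 along one chromosome.

    ``window=None`` returns one row per SNV; otherwise values are averaged
    in half-open windows of ``window`` bp on the 0-based position.
    """
    on_chrom = (table.sites["chrom"] == chrom).to_numpy()
    if not on_chrom.any():
        raise FStatError(f"no sites on chromosome {chrom!r}")
    sub = table.subset_sites(on_chrom)
    pos = sub.sites["pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    sub = sub.subset_sites(order)
    pos = pos[order]
    if config.kind != "f4":
        raise FStatError("f4_scan requires an f4 configuration")
    values = _per_site_values(sub, config)
    if window is None:
        return pd.DataFrame({"chrom": chrom, "pos": pos, "value": values})
    win = (pos - 1) // window
    df = pd.DataFrame({"window": win, "value": values})
    agg = df.groupby("window")["value"].agg(["mean", "count"]).reset_index()
    return pd.DataFrame({
        "chrom": chrom,
        "window_start": agg["window"] * window,
        "window_end": (agg["window"] + 1) * window,
        "value": agg["mean"],
        "n_sites": agg["count"],
    })


# ---------------------------------------------------------------------------
# Welch comparisons
# ---------------------------------------------------------------------------

def welch_t(x: Iterable[float], y: Iterable[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test with Satterthwaite df; two-sided p."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise FStatError("Welch's t-test needs at least 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise FStatError("degenerate Welch test: zero variance, unequal means")
    sx, sy = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(sx + sy)
    df = (sx + sy) ** 2 / (sx ** 2 / (x.size - 1) + sy ** 2 / (y.size - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def contrast_autosome_x(table: AlleleCountTable, config: FStatConfig,
                        partition_autosome: BlockPartition,
                        partition_x: BlockPartition) -> ContrastResult:
    """Compare per-block f4 between autosomes and the (masked) X.

    The test is Welch's t on raw within-block means of per-site f4 values.
    ``x_more_negative`` — the nuclear-swamping expectation under male-biased
    gene flow into the recipient — means the X block mean lies below the
    autosomal one.
    """
    if config.kind != "f4":
        raise FStatError("contrast requires an f4 configuration")
    res_a = f_statistic(table.for_class("autosome"), config,
                        _subset_partition(table, "autosome", partition_autosome))
    res_x = f_statistic(table.for_class("X"), config,
                        _subset_partition(table, "X", partition_x))
    t, df, p = welch_t(res_x.per_block["value"], res_a.per_block["value"])
    diff = res_x.per_block["value"].mean() - res_a.per_block["value"].mean()
    if diff < 0:
        direction = "x_more_negative"
    elif diff > 0:
        direction = "x_less_negative"
    else:
        direction = "none"
    return ContrastResult(config, res_a, res_x, t, df, p, direction)


def _subset_partition(table: AlleleCountTable, chrom_class: str,
                      partition: BlockPartition) -> BlockPartition:
    """Align a partition built on the full site table with a class subset."""
    mask = (table.sites["chrom_class"] == chrom_class).to_numpy()
    if partition.block_ids.shape[0] == int(mask.sum()):
        return partition  # already built on the subset
    if partition.block_ids.shape[0] != mask.shape[0]:
        raise FStatError("partition does not match the site table")
    return BlockPartition(partition.block_ids[mask], partition.blocks,
                          partition.block_size)


def compare_f3(table: AlleleCountTable, config1: FStatConfig,
               config2: FStatConfig,
               partition: BlockPartition) -> tuple[float, float, float, str]:
    """Welch's t between the per-block estimates of two f3 configurations.

    Returns (t, df, p, larger) where ``larger`` names the configuration with
    the greater pooled estimate (more shared drift).
    """
    for cfg in (config1, config2):
        if cfg.kind != "f3_outgroup":
            raise FStatError("compare_f3 requires outgroup-f3 configurations")
    if config1.populations[-1] != config2.populations[-1]:
        raise FStatError("both configurations must share the outgroup")
    r1 = f_statistic(table, config1, partition)
    r2 = f_statistic(table, config2, partition)
    t, df, p = welch_t(r1.per_block["value"], r2.per_block["value"])
    larger = str(config1) if r1.estimate >= r2.estimate else str(config2)
    return t, df, p, larger


def results_to_frame(results: Iterable[FStatResult]) -> pd.DataFrame:
    """Tabulate FStatResults for TSV export."""
    return pd.DataFrame([{
        "config": str(r.config), "estimate": r.estimate, "se": r.se,
        "z": r.z, "p": r.p_value, "n_sites": r.n_sites,
        "n_blocks": r.n_blocks,
    } for r in results])
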