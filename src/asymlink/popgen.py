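"""Microsatellite marker screening and individual inbreeding indices.

Diploid genotype tables (two alleles per locus per individual, scored
in repeat units) support:

* per-locus observed and (small-sample unbiased) expected
  heterozygosity;
* the exact conditional Hardy-Weinberg test (full enumeration of
  genotype arrays given the allele counts where feasible, seeded
  Monte-Carlo permutation otherwise);
* a genotypic linkage-disequilibrium permutation test based on the
  log-likelihood-ratio (G) statistic of the two-locus contingency
  table;
* the Holm step-down multiple-testing adjustment;
* per-individual multilocus heterozygosity (MLH) and mean squared
  allele-span d^2, the two microsatellite inbreeding indices;
* normality-gated two-group comparisons (Welch t when both groups pass
  Shapiro-Wilk, Mann-Whitney U otherwise) with batch Holm correction.

Missing genotypes are dropped pairwise per locus (or locus pair).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeTable",
    "het_stats",
    "hwe_exact",
    "ld_test",
    "holm_adjust",
    "inbreeding_indices",
    "compare_groups",
    "compare_groups_batch",
    "locus_screen",
    "read_genepop",
]

GROUP_FIELDS = ("species", "location", "nest", "pop")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls in repeat units.

    ``a1``/``a2`` are individuals-by-loci DataFrames of allele values
    (NaN = missing call; a call is missing only as a whole pair).
    ``groups`` carries optional per-individual labels (species,
    location, nest). ``motifs`` maps locus name to repeat-motif length;
    when allele calls are loaded in base pairs, dividing by the motif
    puts them on the repeat-unit scale that d^2 assumes.
    """

    a1: pd.DataFrame
    a2: pd.DataFrame
    groups: pd.DataFrame = None
    motifs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.a1.index.equals(self.a2.index) or not self.a1.columns.equals(self.a2.columns):
            raise ValueError("a1 and a2 must share index and columns")
        both = self.a1.notna() == self.a2.notna()
        if not both.all().all():
            raise ValueError("half-missing genotype calls are not allowed")
        if ((self.a1 <= 0) | (self.a2 <= 0)).any().any():
            raise ValueError("allele values must be positive")
        if self.groups is None:
            self.groups = pd.DataFrame(index=self.a1.index)

    @property
    def loci(self) -> list[str]:
        return list(self.a1.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.a1.index)

    def locus_calls(self, locus: str) -> pd.DataFrame:
        """Typed individuals' allele pairs at one locus (columns a1, a2)."""
        calls = pd.DataFrame({"a1": self.a1[locus], "a2": self.a2[locus]}).dropna()
        return calls

    def subset(self, individuals) -> "GenotypeTable":
        return GenotypeTable(
            a1=self.a1.loc[individuals],
            a2=self.a2.loc[individuals],
            groups=self.groups.loc[individuals],
            motifs=self.motifs,
        )

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, motifs: dict | None = None) -> "GenotypeTable":
        """Load a CSV with columns: individual, [group cols], locus cols "a1/a2".

        Missing calls are empty cells, "NA", or "0/0".  When ``motifs``
        is supplied, allele sizes are divided by the motif length at
        load time; otherwise a motif of 1 is assumed with a warning.
        """
        raw = pd.read_csv(path, dtype=str).set_index("individual")
        group_cols = [c for c in raw.columns if c in GROUP_FIELDS]
        locus_cols = [c for c in raw.columns if c not in GROUP_FIELDS]
        a1 = pd.DataFrame(index=raw.index, columns=locus_cols, dtype=float)
        a2 = pd.DataFrame(index=raw.index, columns=locus_cols, dtype=float)
        for locus in locus_cols:
            for ind, cell in raw[locus].items():
                if pd.isna(cell) or cell.strip() in ("", "NA", "0/0"):
                    continue
                try:
                    x, y = cell.split("/")
                    a1.loc[ind, locus] = float(x)
                    a2.loc[ind, locus] = float(y)
                except ValueError:
                    raise ValueError(f"bad genotype cell {cell!r} at ({ind}, {locus})") from None
        motifs = dict(motifs or {})
        if not motifs:
            warnings.warn("no motif lengths supplied; assuming repeat-unit alleles (motif 1)")
        for locus in locus_cols:
            motif = motifs.get(locus, 1)
            if motif != 1:
                a1[locus] = a1[locus] / motif
                a2[locus] = a2[locus] / motif
            motifs[locus] = motif
        return cls(a1=a1, a2=a2, groups=raw[group_cols], motifs=motifs)

    def to_csv(self, path):
        out = self.groups.copy()
        for locus in self.loci:
            motif = self.motifs.get(locus, 1)
            cells = []
            for x, y in zip(self.a1[locus] * motif, self.a2[locus] * motif):
                cells.append("" if pd.isna(x) else f"{x:g}/{y:g}")
            out[locus] = cells
        out.index.name = "individual"
        out.to_csv(path)


def read_genepop(path) -> GenotypeTable:
    """Read a Genepop text file (2- or 3-digit diploid allele encoding).

    "0000"/"000000" codes a missing call.  Population membership is
    recorded in a ``pop`` group column.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh.read().splitlines()]
    if not lines:
        raise ValueError(f"{path}: empty Genepop file")
    body = lines[1:]  # first line is the title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = [t.strip() for t in body[i].split(",") if t.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise ValueError(f"{path}: no locus names before first 'Pop'")
    ids, pops, rows = [], [], []
    pop_no = 0
    for ln in body[i:]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            pop_no += 1
            continue
        if "," not in ln:
            raise ValueError(f"{path}: genotype line without comma: {ln!r}")
        name, _, geno = ln.partition(",")
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(f"{path}: {name.strip()!r} has {len(codes)} genotypes for {len(loci)} loci")
        row = []
        for code in codes:
            if len(code) not in (4, 6):
                raise ValueError(f"{path}: allele code {code!r} is neither 4 nor 6 digits")
            half = len(code) // 2
            x, y = int(code[:half]), int(code[half:])
            row.append((np.nan, np.nan) if x == 0 or y == 0 else (float(x), float(y)))
        ids.append(name.strip())
        pops.append(f"pop{pop_no}")
        rows.append(row)
    index = pd.Index(ids, name="individual")
    a1 = pd.DataFrame([[r[j][0] for j in range(len(loci))] for r in rows], index=index, columns=loci)
    a2 = pd.DataFrame([[r[j][1] for j in range(len(loci))] for r in rows], index=index, columns=loci)
    groups = pd.DataFrame({"pop": pops}, index=index)
    return GenotypeTable(a1=a1, a2=a2, groups=groups)


# ---------------------------------------------------------------------------
# Locus statistics
# ---------------------------------------------------------------------------

def het_stats(table: GenotypeTable, locus: str) -> tuple[float, float]:
    """Observed and unbiased expected heterozygosity at one locus.

    Ho is the fraction of typed individuals that are heterozygous; He
    is Nei's expected heterozygosity with the small-sample correction
    2n/(2n - 1).
    """
    calls = table.locus_calls(locus)
    n = len(calls)
    if n == 0:
        raise ValueError(f"no typed individuals at locus {locus!r}")
    ho = float((calls["a1"] != calls["a2"]).mean())
    alleles = np.concatenate([calls["a1"].to_numpy(), calls["a2"].to_numpy()])
    freqs = pd.Series(alleles).value_counts(normalize=True).to_numpy()
    he = (2 * n / (2 * n - 1)) * (1.0 - float((freqs**2).sum()))
    return ho, he


def _genotype_counts(calls: pd.DataFrame):
    """Allele values, allele counts and the observed genotype-array counts."""
    alleles = np.sort(np.unique(np.concatenate([calls["a1"], calls["a2"]])))
    idx = {a: i for i, a in enumerate(alleles)}
    r = len(alleles)
    arr = np.zeros((r, r), dtype=int)
    for x, y in zip(calls["a1"], calls["a2"]):
        i, j = sorted((idx[x], idx[y]))
        arr[i, j] += 1
    allele_counts = np.zeros(r, dtype=int)
    for i in range(r):
        for j in range(i, r):
            allele_counts[i] += arr[i, j]
            allele_counts[j] += arr[i, j]
    return alleles, allele_counts, arr


def _log_array_prob(arr: np.ndarray, log_const: float) -> float:
    """Log conditional probability of a genotype array given allele counts.

    Levene/Haldane: P = n! * prod(m_j!) * 2^H / ((2n)! * prod(a_ij!)),
    with H the number of heterozygous individuals.  ``log_const``
    carries the array-independent part log(n!) + sum log(m_j!) - log((2n)!).
    """
    r = arr.shape[0]
    h = int(arr.sum() - np.trace(arr))
    log_p = log_const + h * math.log(2.0)
    for i in range(r):
        for j in range(i, r):
            log_p -= math.lgamma(arr[i, j] + 1)
    return log_p


def _enumerate_arrays(allele_counts: np.ndarray, cap: int):
    """Yield all genotype arrays with the given allele counts.

    Arrays are filled row by row; the last cell of each row is forced
    (it must exhaust that allele's remaining count), which prunes the
    search.  Raises RuntimeError if more than ``cap`` arrays exist.
    """
    r = len(allele_counts)
    remaining = allele_counts.astype(int).copy()
    arr = np.zeros((r, r), dtype=int)
    produced = 0
    visited = 0
    node_cap = max(5 * cap, 10_000)

    def rec(i, j):
        nonlocal produced, visited
        visited += 1
        if visited > node_cap:
            raise RuntimeError("enumeration cap exceeded")
        if i == r:
            produced += 1
            if produced > cap:
                raise RuntimeError("enumeration cap exceeded")
            yield arr.copy()
            return
        ni, nj = (i + 1, i + 1) if j == r - 1 else (i, j + 1)
        if i == j == r - 1:
            # final diagonal cell: forced, and the count must be even
            if remaining[i] % 2 == 0:
                cnt = remaining[i] // 2
                arr[i, j] = cnt
                remaining[i] = 0
                yield from rec(ni, nj)
                remaining[i] = 2 * cnt
                arr[i, j] = 0
            return
        if j == r - 1:
            # last cell of row i: must use up allele i's remainder
            cnt = remaining[i]
            if cnt <= remaining[j]:
                arr[i, j] = cnt
                remaining[i] -= cnt
                remaining[j] -= cnt
                yield from rec(ni, nj)
                remaining[i] += cnt
                remaining[j] += cnt
                arr[i, j] = 0
            return
        if i == j:
            for cnt in range(remaining[i] // 2 + 1):
                arr[i, j] = cnt
                remaining[i] -= 2 * cnt
                yield from rec(ni, nj)
                remaining[i] += 2 * cnt
            arr[i, j] = 0
            return
        for cnt in range(min(remaining[i], remaining[j]) + 1):
            arr[i, j] = cnt
            remaining[i] -= cnt
            remaining[j] -= cnt
            yield from rec(ni, nj)
            remaining[i] += cnt
            remaining[j] += cnt
        arr[i, j] = 0

    yield from rec(0, 0)


def hwe_exact(
    table: GenotypeTable,
    locus: str,
    method: str = "auto",
    seed=None,
    n_perm: int = 10_000,
    enumeration_cap: int = 1_000_000,
) -> float:
    """Exact conditional Hardy-Weinberg test at one locus.

    The p-value is the total conditional probability, given the allele
    counts, of genotype arrays no more probable than the observed one.
    With ``method="auto"`` the full array space is enumerated when it
    holds at most ``enumeration_cap`` arrays; otherwise a seeded
    Monte-Carlo permutation (alleles shuffled into pairs, ``n_perm``
    draws, +1-corrected) is used.  A monomorphic locus returns 1.0.
    """
    calls = table.locus_calls(locus)
    if len(calls) == 0:
        raise ValueError(f"no typed individuals at locus {locus!r}")
    alleles, allele_counts, obs = _genotype_counts(calls)
    if len(alleles) < 2:
        return 1.0
    n = len(calls)
    log_const = (
        math.lgamma(n + 1)
        + sum(math.lgamma(m + 1) for m in allele_counts)
        - math.lgamma(2 * n + 1)
    )
    log_p_obs = _log_array_prob(obs, log_const)
    tol = 1e-9

    if method not in ("auto", "enumeration", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")

    if method in ("auto", "enumeration"):
        try:
            p = 0.0
            for arr in _enumerate_arrays(allele_counts, cap=enumeration_cap):
                lp = _log_array_prob(arr, log_const)
                if lp <= log_p_obs + tol:
                    p += math.exp(lp)
            return min(p, 1.0)
        except RuntimeError:
            if method == "enumeration":
                raise ValueError("genotype-array space exceeds the enumeration cap") from None

    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(alleles)), allele_counts)
    hits = 0
    r = len(alleles)
    for _ in range(n_perm):
        rng.shuffle(pool)
        arr = np.zeros((r, r), dtype=int)
        a = np.minimum(pool[0::2], pool[1::2])
        b = np.maximum(pool[0::2], pool[1::2])
        np.add.at(arr, (a, b), 1)
        if _log_array_prob(arr, log_const) <= log_p_obs + tol:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def ld_test(table: GenotypeTable, locus_a: str, locus_b: str, n_perm: int = 1000, seed=None) -> float:
    """Genotypic linkage-disequilibrium permutation test for a locus pair.

    The G (log-likelihood-ratio) statistic of the genotype-by-genotype
    contingency table over individuals typed at both loci is compared
    with its permutation distribution obtained by shuffling one locus's
    genotypes across individuals.  Returns the +1-corrected permutation
    p-value; no phase estimation is attempted.
    """
    ca = table.locus_calls(locus_a)
    cb = table.locus_calls(locus_b)
    shared = ca.index.intersection(cb.index)
    if len(shared) == 0:
        raise ValueError(f"no individual typed at both {locus_a!r} and {locus_b!r}")
    ga = [tuple(sorted(t)) for t in ca.loc[shared].itertuples(index=False)]
    gb = [tuple(sorted(t)) for t in cb.loc[shared].itertuples(index=False)]
    codes_a = pd.factorize(pd.Series(ga).astype(str))[0]
    codes_b = pd.factorize(pd.Series(gb).astype(str))[0]
    na, nb = codes_a.max() + 1, codes_b.max() + 1

    def g_stat(cb_codes):
        obs = np.zeros((na, nb))
        np.add.at(obs, (codes_a, cb_codes), 1.0)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        mask = obs > 0
        return 2.0 * float((obs[mask] * np.log(obs[mask] / exp[mask])).sum())

    g_obs = g_stat(codes_b)
    rng = np.random.default_rng(seed)
    perm = codes_b.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if g_stat(perm) >= g_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sorted ascending, the i-th smallest raw p is multiplied by
    (m - i + 1), a running maximum enforces monotonicity, and values
    are clipped at 1.  Never decreases any p; idempotent on already
    monotone step-down-adjusted vectors.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, np.maximum.accumulate((m - np.arange(m)) * p[order]))
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def inbreeding_indices(table: GenotypeTable) -> pd.DataFrame:
    """Multilocus heterozygosity and mean squared allele distance d^2.

    Per individual: ``mlh`` = heterozygous loci / typed loci and
    ``d2`` = mean over typed loci of the squared allele difference (in
    repeat units).  Individuals with no typed locus are omitted with a
    warning.  Both indices are invariant to locus order and to any
    additive relabelling of alleles.
    """
    typed = table.a1.notna()
    n_typed = typed.sum(axis=1)
    empty = n_typed[n_typed == 0].index.tolist()
    if empty:
        warnings.warn(f"omitting {len(empty)} individual(s) with no typed locus: {empty}")
    keep = n_typed > 0
    het = (table.a1 != table.a2) & typed
    sq = (table.a1 - table.a2) ** 2
    out = pd.DataFrame(
        {
            "mlh": het.sum(axis=1)[keep] / n_typed[keep],
            "d2": sq.mean(axis=1, skipna=True)[keep],
            "n_typed": n_typed[keep].astype(int),
        }
    )
    out.index.name = "individual"
    return out


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def compare_groups(values_by_group: dict, alpha: float = 0.05) -> dict:
    """Two-group comparison with a normality-gated test choice.

    Shapiro-Wilk is applied to each group at ``alpha``; if both groups
    look normal a Welch two-sample t-test is used, otherwise a
    two-sided Mann-Whitney U test.  Returns a dict with the test name,
    statistic (t, or U reported as W) and raw p.
    """
    if len(values_by_group) != 2:
        raise ValueError(f"exactly two groups required, got {len(values_by_group)}")
    (name_a, xs), (name_b, ys) = values_by_group.items()
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 3 or len(ys) < 3:
        raise ValueError("each group needs at least 3 observations")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns on ties / tiny variance
        normal = stats.shapiro(xs).pvalue >= alpha and stats.shapiro(ys).pvalue >= alpha
    if normal:
        res = stats.ttest_ind(xs, ys, equal_var=False)
        return {"groups": (name_a, name_b), "test": "welch_t", "statistic": float(res.statistic), "p": float(res.pvalue)}
    res = stats.mannwhitneyu(xs, ys, alternative="two-sided")
    return {"groups": (name_a, name_b), "test": "mann_whitney_u", "statistic": float(res.statistic), "p": float(res.pvalue)}


def compare_groups_batch(comparisons: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Run a batch of two-group comparisons with Holm correction across them.

    ``comparisons`` maps a comparison name to its two-group dict (see
    :func:`compare_groups`).  Returns a DataFrame with raw and
    Holm-adjusted p-values in input order.
    """
    rows = []
    for name, groups in comparisons.items():
        res = compare_groups(groups, alpha=alpha)
        res["comparison"] = name
        rows.append(res)
    out = pd.DataFrame(rows).set_index("comparison")
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    return out


def locus_screen(table: GenotypeTable, seed=None, n_perm: int = 1000,
                 hwe_n_perm: int = 10_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marker-quality screen: per-locus Ho/He/HWE and pairwise LD.

    Holm correction is applied within the HWE family and within the LD
    family, mirroring standard Genepop-style workflows.  HWE uses full
    enumeration only for small genotype-array spaces (screening-size
    samples go to Monte-Carlo).  Returns ``(locus_stats, ld_stats)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for locus in table.loci:
        ho, he = het_stats(table, locus)
        p = hwe_exact(table, locus, seed=int(rng.integers(2**31)),
                      n_perm=hwe_n_perm, enumeration_cap=20_000)
        rows.append({"locus": locus, "Ho": ho, "He": he, "hwe_p": p})
    locus_stats = pd.DataFrame(rows).set_index("locus")
    locus_stats["hwe_p_holm"] = holm_adjust(locus_stats["hwe_p"].to_numpy())

    pair_rows = []
    loci = table.loci
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            p = ld_test(table, loci[i], loci[j], n_perm=n_perm, seed=int(rng.integers(2**31)))
            pair_rows.append({"locus_a": loci[i], "locus_b": loci[j], "ld_p": p})
    ld_stats = pd.DataFrame(pair_rows)
    if len(ld_stats):
        ld_stats["ld_p_holm"] = holm_adjust(ld_stats["ld_p"].to_numpy())
    return locus_stats, ld_stats
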