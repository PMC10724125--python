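"""Synonymous/nonsynonymous substitution rates for codon sequence pairs.

Two estimators are provided:

* :func:`ng86_pair` — the Nei–Gojobori (1986) counting method.  Synonymous
  and nonsynonymous *sites* are counted per codon (averaged over the two
  sequences), with changes to stop codons excluded from the per-position
  denominator, so S + N = 3 x codons_used exactly.  Differences at
  multi-hit codons are averaged over all minimal mutational pathways that
  avoid stop codons.  Proportions are Jukes–Cantor corrected,
  d = -(3/4)·ln(1 - (4/3)p).

* :func:`ml_pair` — maximum likelihood under a Goldman–Yang-type 61-state
  codon model with transition/transversion ratio kappa, selection
  parameter omega and F3x4 equilibrium frequencies.  The branch length t
  (expected substitutions per codon), kappa and omega are fitted
  numerically; dS and dN follow from the fitted generator by the standard
  expected-substitutions decomposition.

Group-level contrasts use one-way ANOVA with Bonferroni-adjusted pairwise
t tests.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, stats

from ._codons import (CODON_INDEX, NUCLEOTIDES, SENSE_CODONS, STOP_CODONS,
                      is_stop, is_transition, translate_codon)


@dataclass
class DnDsEstimate:
    """dS/dN for one sequence pair.

    ``S``/``N`` are synonymous/nonsynonymous site counts, ``Sd``/``Nd`` the
    corresponding difference counts, ``pS``/``pN`` the proportions and
    ``dS``/``dN`` the corrected rates.  ``omega`` is None when dS is zero
    (flagged).  ``flags`` collects saturation/convergence conditions.
    """

    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None
    method: str
    codons_used: int
    flags: list[str] = field(default_factory=list)
    params: dict[str, float] = field(default_factory=dict)


def _jc_correct(p: float) -> tuple[float, bool]:
    """Jukes–Cantor correction; returns (d, saturated)."""
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Position by position, the fraction of counted single-base changes that
    are synonymous; changes creating a stop codon are excluded from the
    counted set (the denominator), so the two counts always sum to 3.
    """
    codon = codon.upper()
    if codon not in CODON_INDEX:
        raise ValueError(f"{codon!r} is not a sense codon")
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        n_syn = n_counted = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if is_stop(mutant):
                continue
            n_counted += 1
            if translate_codon(mutant) == aa:
                n_syn += 1
        if n_counted:
            syn += n_syn / n_counted
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def _pathway_differences(ca: str, cb: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) difference counts between two
    codons over all minimal stop-free mutational pathways.

    Returns None when every pathway passes through a stop codon.
    """
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    path_counts: list[tuple[int, int]] = []
    for order in itertools.permutations(diffs):
        current = ca
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + cb[pos] + current[pos + 1:]
            if is_stop(nxt):
                ok = False
                break
            if translate_codon(nxt) == translate_codon(current):
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            path_counts.append((sd, nd))
    if not path_counts:
        return None
    sd = sum(p[0] for p in path_counts) / len(path_counts)
    nd = sum(p[1] for p in path_counts) / len(path_counts)
    return sd, nd


def _usable_codon_pairs(a: str, b: str) -> list[tuple[str, str]]:
    """Pairwise-complete sense-codon pairs (gaps/ambiguity/stops dropped)."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    if len(a) % 3:
        raise ValueError("sequence length not a multiple of 3")
    out = []
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue
        out.append((ca, cb))
    return out


def ng86_pair(a: str, b: str, ids: tuple[str, str] = ("a", "b")
              ) -> DnDsEstimate:
    """Nei–Gojobori dS/dN for an in-frame codon sequence pair."""
    pairs = _usable_codon_pairs(a, b)
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in pairs:
        d = _pathway_differences(ca, cb)
        if d is None:
            continue  # all pathways blocked by stops
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        Sd += d[0]
        Nd += d[1]
        used += 1
    if used == 0:
        raise ValueError("no usable codons in pair")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    flags = []
    dS, sat_s = _jc_correct(pS)
    dN, sat_n = _jc_correct(pN)
    if sat_s:
        flags.append("dS_saturated")
    if sat_n:
        flags.append("dN_saturated")
    if dS and not (sat_s or sat_n):
        omega = dN / dS
    else:
        omega = None
        if not (sat_s or sat_n):
            flags.append("omega_undefined")
    return DnDsEstimate(pair=ids, S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                        dS=dS, dN=dN, omega=omega, method="NG86",
                        codons_used=used, flags=flags)


# ---------------------------------------------------------------------------
# F3x4 frequencies and the GY codon model


def f3x4_frequencies(seqs: Iterable[str]) -> np.ndarray:
    """F3x4 codon frequencies over the 61 sense codons.

    Base frequencies are estimated separately at each codon position; each
    codon's frequency is the product of its positional base frequencies,
    renormalized over sense codons.  A zero positional frequency for a
    needed base gets small-count smoothing (with a warning).
    """
    counts = np.zeros((3, 4))
    idx = {b: i for i, b in enumerate(NUCLEOTIDES)}
    for seq in seqs:
        seq = seq.upper()
        for i, base in enumerate(seq):
            k = idx.get(base)
            if k is not None:
                counts[i % 3, k] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases")
    needed = np.zeros((3, 4), dtype=bool)
    for codon in SENSE_CODONS:
        for pos in range(3):
            needed[pos, idx[codon[pos]]] = True
    if np.any(needed & (counts == 0)):
        warnings.warn("zero positional base frequency; smoothing applied",
                      stacklevel=2)
        counts = counts + 0.5
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, idx[c[0]]] * freqs[1, idx[c[1]]]
                   * freqs[2, idx[c[2]]] for c in SENSE_CODONS])
    return pi / pi.sum()


def _codon_change_type() -> tuple[np.ndarray, np.ndarray]:
    """(is_single_transition, is_nonsynonymous) boolean 61x61 matrices for
    codon pairs differing at exactly one position (False elsewhere)."""
    n = len(SENSE_CODONS)
    ts = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    single = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            k = diffs[0]
            ts[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = translate_codon(ci) != translate_codon(cj)
    return single, ts, nonsyn


_SINGLE, _TS, _NONSYN = _codon_change_type()
_SYN = _SINGLE & ~_NONSYN


def gy_rate_matrix(kappa: float, omega: float, pi: np.ndarray
                   ) -> tuple[np.ndarray, float, float]:
    """Goldman–Yang generator, normalized to one expected substitution per
    codon per unit branch length.

    Returns (Q, rho_syn, rho_nonsyn) where the rhos are the equilibrium
    proportions of synonymous and nonsynonymous flux (rho_s + rho_n = 1).
    """
    q = np.zeros_like(_SINGLE, dtype=float)
    q[_SINGLE] = pi[np.nonzero(_SINGLE)[1]]
    q[_TS] *= kappa
    q[_NONSYN & _SINGLE] *= omega
    np.fill_diagonal(q, 0.0)
    flux = pi[:, None] * q
    total = flux.sum()
    q /= total
    flux /= total
    rho_s = flux[_SYN].sum()
    rho_n = flux[_NONSYN].sum()
    np.fill_diagonal(q, -q.sum(axis=1))
    return q, rho_s, rho_n


def _transition_probs(q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """exp(Qt) via eigendecomposition of the pi-symmetrized generator."""
    sqrt_pi = np.sqrt(pi)
    b = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    b = 0.5 * (b + b.T)  # clean numerical asymmetry
    w, v = linalg.eigh(b)
    expm = (v * np.exp(w * t)) @ v.T
    p = expm / sqrt_pi[:, None] * sqrt_pi[None, :]
    return np.clip(p, 1e-300, None)


def _sites_f3x4(kappa: float, pi: np.ndarray) -> float:
    """Proportion of synonymous sites under the mutational (omega = 1)
    model; S per codon is 3x this."""
    _, rho_s, _ = gy_rate_matrix(kappa, 1.0, pi)
    return rho_s


def ml_pair(a: str, b: str, ids: tuple[str, str] = ("a", "b"),
            max_iter: int = 500) -> DnDsEstimate:
    """Pairwise ML estimate under the GY-F3x4 codon model.

    Maximizes the likelihood of the codon-pair pattern counts over
    (t, kappa, omega) from the fixed start (0.1, 2, 0.2); dS and dN come
    from the fitted generator's expected-substitutions decomposition.
    The model is time-reversible, so the pair order does not matter.
    """
    pairs = _usable_codon_pairs(a, b)
    if not pairs:
        raise ValueError("no usable codons in pair")
    pi = f3x4_frequencies([ "".join(p[0] for p in pairs),
                            "".join(p[1] for p in pairs) ])
    n = len(SENSE_CODONS)
    counts = np.zeros((n, n))
    for ca, cb in pairs:
        counts[CODON_INDEX[ca], CODON_INDEX[cb]] += 1.0
    nz = counts > 0

    def neg_loglik(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        if t > 50 or kappa > 500 or omega > 500:
            return 1e12
        q, _, _ = gy_rate_matrix(kappa, omega, pi)
        p = _transition_probs(q, pi, t)
        joint = pi[:, None] * p
        return -float(np.sum(counts[nz] * np.log(joint[nz])))

    x0 = np.log([0.1, 2.0, 0.2])
    res = optimize.minimize(neg_loglik, x0, method="Nelder-Mead",
                            options={"maxiter": max_iter, "xatol": 1e-6,
                                     "fatol": 1e-8})
    t, kappa, omega_hat = np.exp(res.x)
    flags = []
    if not res.success:
        flags.append("not_converged")
    if omega_hat < 1e-4 or omega_hat > 100 or kappa > 400:
        flags.append("boundary")
    q, rho_s, rho_n = gy_rate_matrix(kappa, omega_hat, pi)
    rho_s1 = _sites_f3x4(kappa, pi)
    used = len(pairs)
    S = 3.0 * rho_s1 * used
    N = 3.0 * (1.0 - rho_s1) * used
    # expected substitutions per codon, split by class, over sites
    dS = t * rho_s / (3.0 * rho_s1)
    dN = t * rho_n / (3.0 * (1.0 - rho_s1))
    Sd = sum(ca != cb and _SYN[CODON_INDEX[ca], CODON_INDEX[cb]]
             for ca, cb in pairs)
    Nd = sum(ca != cb and not _SYN[CODON_INDEX[ca], CODON_INDEX[cb]]
             for ca, cb in pairs)
    omega = dN / dS if dS > 0 else None
    if omega is None:
        flags.append("omega_undefined")
    return DnDsEstimate(pair=ids, S=S, N=N, Sd=float(Sd), Nd=float(Nd),
                        pS=Sd / S if S else 0.0, pN=Nd / N if N else 0.0,
                        dS=float(dS), dN=float(dN), omega=omega,
                        method="ML-F3x4", codons_used=used, flags=flags,
                        params={"t": float(t), "kappa": float(kappa),
                                "omega": float(omega_hat),
                                "loglik": -float(res.fun)})


def simulate_gy_pair(t: float, kappa: float, omega: float, pi: np.ndarray,
                     n_codons: int, rng: np.random.Generator
                     ) -> tuple[str, str]:
    """Simulate a codon-sequence pair from the GY model (oracle for
    :func:`ml_pair` recovery tests)."""
    q, _, _ = gy_rate_matrix(kappa, omega, pi)
    p = _transition_probs(q, pi, t)
    i = rng.choice(len(SENSE_CODONS), size=n_codons, p=pi / pi.sum())
    j = np.array([rng.choice(len(SENSE_CODONS), p=p[k] / p[k].sum())
                  for k in i])
    a = "".join(SENSE_CODONS[k] for k in i)
    b = "".join(SENSE_CODONS[k] for k in j)
    return a, b


# ---------------------------------------------------------------------------
# Group statistics


@dataclass
class GroupComparison:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t tests."""

    metric: str
    group_stats: dict[str, tuple[float, float | None, int]]  # mean, sd, n
    anova: tuple[float, int, int, float]  # F, df1, df2, p
    pairwise: "object"  # DataFrame of adjusted p-values
    flags: list[str] = field(default_factory=list)
    excluded_singletons: list[str] = field(default_factory=list)


def group_compare(values: Mapping[str, float], grouping: Mapping[str, str],
                  metric: str = "value") -> GroupComparison:
    """Compare a per-sample metric across groups.

    Groups with a single member are excluded (and listed); the ANOVA needs
    at least two groups with two or more members each.  Pairwise p-values
    are Bonferroni-multiplied by the number of comparisons, capped at 1.
    """
    import pandas as pd

    by_group: dict[str, list[float]] = {}
    for sample, val in values.items():
        if sample not in grouping:
            raise KeyError(f"sample {sample!r} has no group assignment")
        by_group.setdefault(grouping[sample], []).append(float(val))
    singletons = [g for g, v in by_group.items() if len(v) < 2]
    kept = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(kept) < 2:
        raise ValueError("ANOVA needs at least two groups with >= 2 members")
    flags: list[str] = []
    groups = list(kept)
    arrays = [np.asarray(kept[g]) for g in groups]
    all_vals = np.concatenate(arrays)
    df1 = len(groups) - 1
    df2 = len(all_vals) - len(groups)
    if np.allclose(all_vals, all_vals[0]):
        flags.append("zero_variance")
        F, p = 0.0, math.nan
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*arrays)
        F, p = float(F), float(p)
    k = len(groups) * (len(groups) - 1) // 2
    pmat = pd.DataFrame(np.nan, index=groups, columns=groups)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            xa, xb = kept[ga], kept[gb]
            if np.allclose(xa, np.mean(xa)) and np.allclose(xb, np.mean(xb)) \
                    and math.isclose(np.mean(xa), np.mean(xb)):
                raw = 1.0
            else:
                _, raw = stats.ttest_ind(xa, xb)
            adj = min(1.0, float(raw) * k)
            pmat.loc[ga, gb] = pmat.loc[gb, ga] = adj
    group_stats = {}
    for g, v in by_group.items():
        arr = np.asarray(v)
        sd = float(np.std(arr, ddof=1)) if len(arr) >= 2 else None
        group_stats[g] = (float(arr.mean()), sd, len(arr))
    return GroupComparison(metric=metric, group_stats=group_stats,
                           anova=(F, df1, df2, p), pairwise=pmat,
                           flags=flags, excluded_singletons=singletons)


def estimates_vs_reference(aln_rows: Sequence[tuple[str, str]],
                           reference_id: str, method: str = "ng86"
                           ) -> list[DnDsEstimate]:
    """dS/dN of every row against the reference row of a codon alignment.

    Gap codons and ambiguous codons are removed pairwise inside the
    estimators.
    """
    rows = dict(aln_rows)
    ref = rows.pop(reference_id)
    fn = ng86_pair if method == "ng86" else ml_pair
    return [fn(seq, ref, ids=(taxon, reference_id))
            for taxon, seq in rows.items()]
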