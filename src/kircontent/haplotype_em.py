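"""Haplotype-frequency estimation from presence/absence genotypes by EM.

A gene-content genotype is the locus-wise OR of two haplotypes, so unlike
SNP phasing the pair is ambiguous even for "homozygous" patterns: a locus
observed present may sit on one or both chromosomes. This module
maximizes the multinomial likelihood of the observed genotypes over
haplotype frequencies under random (Hardy-Weinberg) pairing:

    P(genotype g) = sum over unordered pairs (h1, h2) with h1 OR h2 = g of
                    f(h1) f(h2) (2 - delta_{h1 h2})

with the classic EM recursion: posterior pair responsibilities per
individual (E-step), then frequencies set to half the expected haplotype
dosage (M-step). The log-likelihood is non-decreasing at every iteration.

Presence/absence OR-genotypes can leave frequency combinations
non-identifiable (flat likelihood directions); candidates along which the
curvature of the log-likelihood is numerically zero are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import GenotypePanel, HaplotypeTable

__all__ = [
    "EMResult",
    "enumerate_candidate_haplotypes",
    "em_frequencies",
]


@dataclass
class EMResult:
    table: HaplotypeTable
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    flat_directions: list[str] = field(default_factory=list)


def _to_masks(matrix: np.ndarray) -> list[int]:
    masks = []
    for row in matrix:
        m = 0
        for j, bit in enumerate(row):
            if bit:
                m |= 1 << j
        masks.append(m)
    return masks


def _mask_to_vector(mask: int, n_loci: int) -> np.ndarray:
    return np.array([(mask >> j) & 1 for j in range(n_loci)], dtype=bool)


def enumerate_candidate_haplotypes(
    panel: GenotypePanel, cap: int = 4096, unrelated_only: bool = False
) -> np.ndarray:
    """All presence vectors compatible with at least one individual.

    A vector v is a candidate when v <= g (bitwise) for some observed
    genotype g: it can then always serve as half of a compatible pair
    (its partner g completes the OR). The empty vector — a minimal,
    framework-only haplotype — is therefore always a candidate. Raises
    when the candidate count exceeds ``cap``; restrict loci or supply
    candidates explicitly in that case.
    """
    matrix = panel.select(unrelated_only)
    n_loci = matrix.shape[1]
    seen: set[int] = set()
    for g in sorted(set(_to_masks(matrix)), key=lambda m: -bin(m).count("1")):
        if g in seen:
            continue
        # enumerate submasks of g
        s = g
        while True:
            seen.add(s)
            if s == 0:
                break
            s = (s - 1) & g
            if len(seen) > cap:
                raise ValueError(
                    f"candidate count exceeds cap={cap}; restrict loci or "
                    "supply a candidate list"
                )
    if len(seen) > cap:
        raise ValueError(
            f"candidate count exceeds cap={cap}; restrict loci or supply a candidate list"
        )
    masks = sorted(seen)
    return np.array([_mask_to_vector(m, n_loci) for m in masks], dtype=bool)


def em_frequencies(
    panel: GenotypePanel,
    candidates: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
    cap: int = 4096,
    unrelated_only: bool = False,
    seed: int | None = None,
) -> EMResult:
    """Maximum-likelihood haplotype frequencies for a panel.

    ``candidates`` is a boolean (n_candidates × n_loci) array; when None
    they are enumerated from the panel. Initialization is uniform over
    candidates (deterministic); pass ``seed`` for a random Dirichlet start
    instead, useful for escaping likelihood plateaus. Iteration stops when
    the largest frequency change drops below ``tol``.
    """
    matrix = panel.select(unrelated_only)
    ids = (
        [i for i, keep in zip(panel.individuals, panel.unrelated_mask) if keep]
        if unrelated_only
        else list(panel.individuals)
    )
    if candidates is None:
        candidates = enumerate_candidate_haplotypes(panel, cap=cap, unrelated_only=unrelated_only)
    candidates = np.asarray(candidates, dtype=bool)
    n_cand = candidates.shape[0]
    if n_cand == 0:
        raise ValueError("no candidate haplotypes")
    cand_masks = _to_masks(candidates)

    # group individuals by genotype and precompute compatible pairs per genotype
    geno_masks = _to_masks(matrix)
    counts: dict[int, int] = {}
    first_ind: dict[int, str] = {}
    for ind, g in zip(ids, geno_masks):
        counts[g] = counts.get(g, 0) + 1
        first_ind.setdefault(g, ind)

    pair_index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for g in counts:
        subs = [i for i, m in enumerate(cand_masks) if (m & ~g) == 0]
        ii, jj = [], []
        for a_pos, i in enumerate(subs):
            for j in subs[a_pos:]:
                if cand_masks[i] | cand_masks[j] == g:
                    ii.append(i)
                    jj.append(j)
        if not ii:
            raise ValueError(
                f"genotype of individual {first_ind[g]!r} is not expressible "
                "as an OR of two candidates"
            )
        pair_index[g] = (np.array(ii), np.array(jj))

    total_n = sum(counts.values())
    if seed is None:
        freqs = np.full(n_cand, 1.0 / n_cand)
    else:
        freqs = np.random.default_rng(seed).dirichlet(np.ones(n_cand))

    def loglik_of(f: np.ndarray) -> float:
        ll = 0.0
        for g, n_g in counts.items():
            ii, jj = pair_index[g]
            w = f[ii] * f[jj] * np.where(ii == jj, 1.0, 2.0)
            p = w.sum()
            if p <= 0.0:
                return -np.inf
            ll += n_g * np.log(p)
        return ll

    trace = [loglik_of(freqs)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        dosage = np.zeros(n_cand)
        for g, n_g in counts.items():
            ii, jj = pair_index[g]
            w = freqs[ii] * freqs[jj] * np.where(ii == jj, 1.0, 2.0)
            p = w.sum()
            if p <= 0.0:
                raise ValueError("likelihood vanished during EM (degenerate start)")
            r = n_g * w / p
            np.add.at(dosage, ii, r)
            np.add.at(dosage, jj, r)
        new = dosage / (2.0 * total_n)
        delta = float(np.max(np.abs(new - freqs)))
        freqs = new
        trace.append(loglik_of(freqs))
        if delta < tol:
            converged = True
            break

    names = tuple(f"EH{i + 1}" for i in range(n_cand))
    freqs = np.clip(freqs, 0.0, None)
    freqs = freqs / freqs.sum()
    table = HaplotypeTable(panel.registry, names, candidates, freqs)
    flat = _flat_directions(loglik_of, freqs, names)
    return EMResult(
        table=table,
        loglik=trace[-1],
        n_iter=it,
        converged=converged,
        loglik_trace=trace,
        flat_directions=flat,
    )


def _flat_directions(loglik_of, freqs: np.ndarray, names, eps: float = 1e-4) -> list[str]:
    """Candidates with numerically zero log-likelihood curvature.

    Curvature is measured along the simplex-preserving direction
    e_h - f by a central second difference; |curvature| < 1e-6 marks a
    flat (non-identifiable) direction.
    """
    flat = []
    base = loglik_of(freqs)
    for h, name in enumerate(names):
        d = -freqs.copy()
        d[h] += 1.0
        up = loglik_of(np.clip(freqs + eps * d, 0.0, None))
        dn = loglik_of(np.clip(freqs - eps * d, 0.0, None))
        if not np.isfinite(up) or not np.isfinite(dn):
            continue
        curv = (up - 2.0 * base + dn) / eps**2
        if abs(curv) < 1e-6:
            flat.append(name)
    return flat
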