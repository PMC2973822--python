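"""C1/C2/Bw4 epitope classification and the V76/N80 co-occurrence test.

The KIR-binding epitopes of MHC-B and -C allotypes are determined by two
alpha-1 domain residues of the mature protein:

* **C1** = valine 76 with asparagine 80 (MHC-B and -C);
* **C2** = valine 76 with lysine 80 (MHC-C);
* **Bw4** = isoleucine or threonine 80 (HLA-B allotypes, ligand of
  KIR3DL1). V76 combined with I80/T80 perturbs Bw4 recognition without
  creating C1 or C2; such combinations classify as Bw4 with a conflict
  flag.

The binomial co-occurrence test asks whether the substitutions that
recurrently created V76 could have landed on N80-carrying allotypes every
time by chance, given the fraction of allotypes with an N80 background.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .core_model import UNKNOWN_RESIDUE, ResiduePair

__all__ = [
    "EpitopeCall",
    "classify_epitope",
    "epitope_frequencies",
    "binomial_cooccurrence_test",
]


@dataclass(frozen=True)
class EpitopeCall:
    name: str
    epitope: str  # one of {"C1", "C2", "Bw4", "none"}
    flags: frozenset[str] = frozenset()


def classify_epitope(pair: ResiduePair) -> EpitopeCall:
    """Apply the residue-76/80 rule table.

    An unknown residue at either position yields ``none`` with the
    ``unknown_residue`` flag; V76 on an I80/T80 (Bw4) background yields
    ``Bw4`` flagged ``v76_with_bw4_position``.
    """
    r76, r80 = pair.residue76, pair.residue80
    if UNKNOWN_RESIDUE in (r76, r80):
        return EpitopeCall(pair.name, "none", frozenset({"unknown_residue"}))
    if r80 in ("I", "T"):
        flags = frozenset({"v76_with_bw4_position"}) if r76 == "V" else frozenset()
        return EpitopeCall(pair.name, "Bw4", flags)
    if r76 == "V" and r80 == "N":
        return EpitopeCall(pair.name, "C1")
    if r76 == "V" and r80 == "K":
        return EpitopeCall(pair.name, "C2")
    return EpitopeCall(pair.name, "none")


def epitope_frequencies(pairs: list[ResiduePair]) -> dict[str, float]:
    """Epitope fractions over classifiable allotypes.

    Records with an unknown residue are excluded from the denominator;
    their count is reported under ``n_unknown``. Fractions (over the
    classified records) sum to 1.
    """
    if not pairs:
        raise ValueError("empty allotype list")
    calls = [classify_epitope(p) for p in pairs]
    known = [c for c in calls if "unknown_residue" not in c.flags]
    out: dict[str, float] = {"n_unknown": float(len(calls) - len(known))}
    if known:
        for epi in ("C1", "C2", "Bw4", "none"):
            out[epi] = sum(1 for c in known if c.epitope == epi) / len(known)
    return out


def binomial_cooccurrence_test(
    k_on_background: int, k_total: int, background_fraction: float
) -> float:
    """Upper-tail binomial probability of k events on a given background.

    Returns P(X >= k_on_background) for X ~ Binomial(k_total,
    background_fraction): the chance that at least that many independent
    substitutions land on background-carrying allotypes. One-sided because
    the hypothesis is directional (the events *always* occurred on the
    background). With k_on_background = k_total this reduces to
    background_fraction ** k_total.
    """
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction outside [0, 1]")
    if k_total < 0 or not 0 <= k_on_background <= k_total:
        raise ValueError("need 0 <= k_on_background <= k_total")
    if k_on_background == 0:
        return 1.0
    return float(stats.binom.sf(k_on_background - 1, k_total, background_fraction))
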