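"""ANDI: the average number of distinct KIR2DL-HLA interactions.

ANDI summarizes, per population, the expected number of distinct
receptor-ligand pairings between the inhibitory lineage III receptors
KIR2DL1-3 and the C1/C2 epitopes of their HLA ligands, from phenotype
(carrier) frequencies PF:

    base:  2DL1*C2 + 2DL2*C2 + 2DL2*C1 + 2DL3*C1

The ``b46`` model adds, for populations carrying the C1-bearing HLA-B*46
allotype (East/Southeast Asia), the 2DL2-3 interactions with B*46:
2DL2*B46 + 2DL3*B46. The ``alternative`` model drops the weak 2DL2-C2
term; ``alternative+b46`` combines both changes.

``hwe_max_andi`` gives the ceiling a population could reach by tuning its
HLA-C composition: C1/C2 are treated as a biallelic epitope system at
HLA-C (every allele carries exactly one of the two epitopes), phenotype
frequencies follow Hardy-Weinberg from the C1 allele frequency c, and the
C-terms are maximized over c in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core_model import FrequencyTable

__all__ = [
    "MODELS",
    "AndiResult",
    "compute_andi",
    "andi_table",
    "andi_summary",
    "hwe_max_andi",
    "pearson_correlation",
]

MODELS = ("base", "b46", "alternative", "alternative+b46")

#: (receptor, ligand) terms per model; the B46 terms are appended for the
#: b46 variants only when the population's use_b46 flag is set.
_C_TERMS = {
    "base": (("2DL1", "C2"), ("2DL2", "C2"), ("2DL2", "C1"), ("2DL3", "C1")),
    "alternative": (("2DL1", "C2"), ("2DL2", "C1"), ("2DL3", "C1")),
}
_B46_TERMS = (("2DL2", "B46"), ("2DL3", "B46"))


def _model_terms(model: str, with_b46: bool):
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    c_terms = _C_TERMS["alternative" if model.startswith("alternative") else "base"]
    b46 = _B46_TERMS if (model.endswith("b46") and with_b46) else ()
    return c_terms + b46


@dataclass(frozen=True)
class AndiResult:
    population: str
    andi: float
    terms: dict[str, float]
    model: str


def compute_andi(row, model: str = "base") -> AndiResult:
    """ANDI for one population row (mapping or pandas Series).

    The row supplies phenotype frequencies under keys 2DL1, 2DL2, 2DL3,
    C1, C2 and (for the b46 models) B46; B*46 terms are included only when
    the row's ``use_b46`` flag is true (default: B46 > 0).
    """
    get = row.get
    with_b46 = bool(get("use_b46", float(get("B46", 0.0) or 0.0) > 0.0))
    terms = {}
    for receptor, ligand in _model_terms(model, with_b46):
        try:
            r, l = float(get(receptor)), float(get(ligand))
        except (KeyError, TypeError):
            raise KeyError(f"model {model!r} needs keys {receptor!r} and {ligand!r}") from None
        if not (0.0 <= r <= 1.0 and 0.0 <= l <= 1.0):
            raise ValueError(f"frequency outside [0, 1] in term {receptor}*{ligand}")
        terms[f"{receptor}*{ligand}"] = r * l
    name = str(get("population", "") or "")
    return AndiResult(name, float(sum(terms.values())), terms, model)


def andi_table(table: FrequencyTable, model: str = "base") -> list[AndiResult]:
    """ANDI for every population of a frequency table."""
    return [compute_andi(row, model) for _, row in table.data.iterrows()]


def andi_summary(table: FrequencyTable, model: str = "base") -> dict:
    """Distribution of ANDI over populations and over group labels.

    Per-population: min, max, median and the 25-75 percentile band.
    Per-group: the group medians plus the same statistics over them —
    the published range statements aggregate populations into regional
    groups, so both granularities are reported.
    """
    results = andi_table(table, model)
    if not results:
        raise ValueError("empty frequency table")
    values = np.array([r.andi for r in results])
    groups = table.data["group"].to_numpy()
    group_medians = {
        g: float(np.median(values[groups == g])) for g in dict.fromkeys(groups)
    }
    gvals = np.array(list(group_medians.values()))

    def stats_of(x):
        return {
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "median": float(np.median(x)),
            "p25": float(np.percentile(x, 25)),
            "p75": float(np.percentile(x, 75)),
            "n": int(len(x)),
        }

    return {
        "model": model,
        "per_population": stats_of(values),
        "per_group": stats_of(gvals),
        "group_medians": group_medians,
        "values": {r.population: r.andi for r in results},
    }


def hwe_max_andi(
    kir_pf: dict[str, float],
    model: str = "base",
    b46_pf: float = 0.0,
) -> float:
    """Maximum ANDI over HLA-C compositions under Hardy-Weinberg.

    With c the C1 allele frequency at HLA-C, phenotype frequencies are
    C1 = 1-(1-c)^2 and C2 = 1-c^2; the model's C-terms are maximized over
    c in [0, 1] by bounded scalar optimization. B*46 is not an HLA-C
    allele, so its terms are held at the supplied ``b46_pf`` rather than
    optimized.
    """
    for key in ("2DL1", "2DL2", "2DL3"):
        v = float(kir_pf[key])
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{key} frequency outside [0, 1]")
    if not 0.0 <= b46_pf <= 1.0:
        raise ValueError("B46 frequency outside [0, 1]")

    def andi_at(c: float) -> float:
        row = dict(kir_pf)
        row.update(
            population="",
            C1=1.0 - (1.0 - c) ** 2,
            C2=1.0 - c**2,
            B46=b46_pf,
            use_b46=b46_pf > 0.0,
        )
        return compute_andi(row, model).andi

    res = optimize.minimize_scalar(
        lambda c: -andi_at(c), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    best = -float(res.fun)
    # the objective is a quadratic in c; guard the endpoints explicitly
    return max(best, andi_at(0.0), andi_at(1.0))


def pearson_correlation(
    x, y, leave_one_out: bool = False
) -> float | tuple[float, list[float]]:
    """Pearson product-moment correlation coefficient.

    With ``leave_one_out`` also returns the coefficient recomputed with
    each point removed, a quick screen for single-population outliers
    driving a correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance")
    r = float(stats.pearsonr(x, y)[0])
    if not leave_one_out:
        return r
    loo = []
    for i in range(x.size):
        mask = np.arange(x.size) != i
        loo.append(float(stats.pearsonr(x[mask], y[mask])[0]))
    return r, loo
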