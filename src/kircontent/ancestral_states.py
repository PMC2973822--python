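"""Parsimony counting of character-state changes on a tree.

Given a tree with a single-character state at every tip (for example the
residue at position 76 of an MHC class I alignment), Sankoff's
small-parsimony dynamic programme with unit costs yields the minimum
number of state changes required to explain the tips. Unit-cost Sankoff
rather than Fitch is used so polytomies and alphabets larger than two
need no special-casing.

Because different most-parsimonious reconstructions (MPRs) can attribute
changes to different directions (the classic ACCTRAN/DELTRAN ambiguity),
per-transition counts are reported as [min, max] ranges over all MPRs.
The ranges are exact at any tree size: for each ordered transition the
Sankoff recursion is re-run on lexicographic (total changes, transition
count) costs, which minimizes or maximizes that transition's count among
reconstructions achieving the global minimum. Minimum counts are
lower-bound statements — "at least this many events" — not likelihood
reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import TipStateTree

__all__ = [
    "ChangeCount",
    "parsimony_changes",
    "count_reversions",
]


@dataclass
class ChangeCount:
    min_changes: int
    #: (from_state, to_state) -> (min, max) count over all MPRs
    per_transition: dict[tuple[str, str], tuple[int, int]]
    #: one chosen assignment: tip label or internal tip-set signature -> state
    reconstruction: dict[object, str]
    root_state: str


def _alphabet(tree: TipStateTree, extra: tuple[str, ...] = ()) -> list[str]:
    return sorted(set(tree.states.values()) | {s for s in extra if s})


def _sankoff_pair(tree: TipStateTree, alphabet: list[str], transition=None, sign=1):
    """Sankoff with lexicographic (changes, sign*transition_count) costs.

    With ``transition=None`` the secondary component is zero everywhere and
    the recursion is plain unit-cost Sankoff. Otherwise the secondary
    component counts edges whose (parent, child) states equal
    ``transition``; ``sign=+1`` finds the MPR-minimum of that count,
    ``sign=-1`` the MPR-maximum.
    """
    k = len(alphabet)
    index = {s: i for i, s in enumerate(alphabet)}
    INF = float("inf")
    primary: dict[int, np.ndarray] = {}
    secondary: dict[int, np.ndarray] = {}
    ta = index[transition[0]] if transition else -1
    tb = index[transition[1]] if transition else -1
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            p = np.full(k, INF)
            s = np.zeros(k)
            p[index[tree.states[node.taxon.label]]] = 0.0
            primary[id(node)], secondary[id(node)] = p, s
            continue
        p = np.zeros(k)
        s = np.zeros(k)
        for child in node.child_nodes():
            cp, cs = primary[id(child)], secondary[id(child)]
            for a in range(k):
                best_p, best_s = INF, INF
                for b in range(k):
                    ep = cp[b] + (0.0 if a == b else 1.0)
                    es = cs[b] + (sign if (a == ta and b == tb) else 0.0)
                    if ep < best_p or (ep == best_p and es < best_s):
                        best_p, best_s = ep, es
                p[a] += best_p
                s[a] += best_s
        primary[id(node)], secondary[id(node)] = p, s
    return primary, secondary, index


def _root_choice(primary, secondary, index, root_state, root_id):
    p, s = primary[root_id], secondary[root_id]
    best = p.min()
    if root_state is not None:
        i = index[root_state]
        if p[i] > best:
            raise ValueError(
                f"root_state {root_state!r} is incompatible with every "
                f"most-parsimonious reconstruction (cost {p[i]:.0f} > {best:.0f})"
            )
        return i, p[i], s[i]
    # among MPR-compatible root states, take the secondary optimum
    candidates = [i for i in range(len(p)) if p[i] == best]
    i = min(candidates, key=lambda i: s[i])
    return i, p[i], s[i]


def _backtrack(tree: TipStateTree, alphabet, primary, root_index) -> dict[int, int]:
    """One MPR: preorder assignment preferring the parent's state on ties."""
    assign: dict[int, int] = {}
    root = tree.tree.seed_node
    assign[id(root)] = root_index
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a = assign[id(node.parent_node)]
        cp = primary[id(node)]
        best = min(cp[b] + (0.0 if a == b else 1.0) for b in range(len(alphabet)))
        # prefer keeping the parent state (DELTRAN-style late changes)
        if cp[a] == best:
            assign[id(node)] = a
        else:
            assign[id(node)] = int(
                min(
                    (b for b in range(len(alphabet)) if cp[b] + (0.0 if a == b else 1.0) == best),
                    key=lambda b: alphabet[b],
                )
            )
    return assign


def _signature(node):
    if node.is_leaf():
        return node.taxon.label
    return frozenset(l.taxon.label for l in node.leaf_iter())


def parsimony_changes(tree: TipStateTree, root_state: str | None = None) -> ChangeCount:
    """Minimum change count and per-transition MPR ranges.

    ``root_state``, when given, constrains the root's state; it must be
    achievable by a most-parsimonious reconstruction, otherwise an error
    reports the conflict (the constraint is never forced at extra cost).
    """
    alphabet = _alphabet(tree, (root_state,) if root_state else ())
    primary, secondary, index = _sankoff_pair(tree, alphabet)
    root = tree.tree.seed_node
    root_index, min_changes, _ = _root_choice(primary, secondary, index, root_state, id(root))

    per_transition: dict[tuple[str, str], tuple[int, int]] = {}
    for a in alphabet:
        for b in alphabet:
            if a == b:
                continue
            lo = _transition_extreme(tree, alphabet, (a, b), root_state, sign=1)
            hi = _transition_extreme(tree, alphabet, (a, b), root_state, sign=-1)
            if hi > 0:
                per_transition[(a, b)] = (lo, hi)

    assign = _backtrack(tree, alphabet, primary, root_index)
    reconstruction = {
        _signature(node): alphabet[assign[id(node)]]
        for node in tree.tree.preorder_node_iter()
    }
    return ChangeCount(
        min_changes=int(min_changes),
        per_transition=per_transition,
        reconstruction=reconstruction,
        root_state=alphabet[root_index],
    )


def _transition_extreme(tree, alphabet, transition, root_state, sign) -> int:
    primary, secondary, index = _sankoff_pair(tree, alphabet, transition, sign)
    root = tree.tree.seed_node
    _, _, sec = _root_choice(primary, secondary, index, root_state, id(root))
    return int(round(sign * sec))


def count_reversions(
    tree: TipStateTree,
    ancestral: str,
    derived: str,
    root_state: str | None = None,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Ranges of gains (ancestral -> derived) and losses (derived -> ancestral).

    Computed over all most-parsimonious reconstructions, optionally with
    the root constrained to ``root_state`` (typically the ancestral
    state). Returns ``((gain_min, gain_max), (loss_min, loss_max))``.
    """
    if len(ancestral) != 1 or len(derived) != 1:
        raise ValueError("states are single characters")
    alphabet = _alphabet(tree, (ancestral, derived, root_state or ""))
    gains = tuple(
        _transition_extreme(tree, alphabet, (ancestral, derived), root_state, sign)
        for sign in (1, -1)
    )
    losses = tuple(
        _transition_extreme(tree, alphabet, (derived, ancestral), root_state, sign)
        for sign in (1, -1)
    )
    return (gains[0], gains[1]), (losses[0], losses[1])
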