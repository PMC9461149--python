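"""Scoring a predicted domain assignment against reference assignments.

Two measures: the domain overlap (OL) score — the fraction of residues
placed in the same domain under the optimal one-to-one matching between
predicted and reference domains, defined only when the domain counts agree
— and the adjusted Rand index (ARI), a chance-corrected partition agreement
computed from the contingency table, defined for any pair of partitions.
Verdicts (correct / overcut / undercut / boundary-inconsistency / other)
follow the usual benchmark convention against one or two references.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb

from .partition import DomainAssignment


class OLUndefined(ValueError):
    """OL score is undefined when predicted/reference domain counts differ."""


def labels_on_common_support(
    pred: DomainAssignment, ref: DomainAssignment
) -> tuple[np.ndarray, np.ndarray, int]:
    """Label arrays restricted to residues covered by both assignments.

    Residues assigned in only one of the two (e.g. unresolved in a
    reference) are excluded; the exclusion count is returned and logged.
    """
    import logging

    pmap, rmap = pred.residue_map(), ref.residue_map()
    common = sorted(pmap.keys() & rmap.keys())
    if not common:
        raise ValueError("assignments share no residues")
    excluded = len(pmap.keys() | rmap.keys()) - len(common)
    if excluded:
        logging.getLogger(__name__).warning(
            "%d residues excluded from evaluation (not covered by both "
            "assignments)", excluded,
        )
    p = np.array([pmap[r] for r in common])
    r = np.array([rmap[r] for r in common])
    return p, r, excluded


def _labels_of(assignment: DomainAssignment | np.ndarray) -> np.ndarray:
    if isinstance(assignment, DomainAssignment):
        return assignment.labels()
    return np.asarray(assignment, dtype=int)


def contingency_table(pred, ref) -> np.ndarray:
    """Counts n_ij of residues in predicted domain i and reference domain j."""
    p = _labels_of(pred)
    r = _labels_of(ref)
    if p.shape != r.shape:
        raise ValueError(
            f"residue universes differ: {p.shape[0]} vs {r.shape[0]} residues"
        )
    pu, pi = np.unique(p, return_inverse=True)
    ru, ri = np.unique(r, return_inverse=True)
    table = np.zeros((len(pu), len(ru)), dtype=int)
    np.add.at(table, (pi, ri), 1)
    return table


def ol_score(pred, ref) -> float:
    """Overlap score under the optimal one-to-one domain matching.

    Builds the (square) overlap table and maximizes the matched residue
    count with an optimal-assignment solve; raises :class:`OLUndefined`
    when the two assignments have different domain counts.
    """
    table = contingency_table(pred, ref)
    if table.shape[0] != table.shape[1]:
        raise OLUndefined(
            f"domain counts differ ({table.shape[0]} vs {table.shape[1]}); "
            "OL score undefined"
        )
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / table.sum())


def ol_score_exhaustive(table: np.ndarray) -> float:
    """Brute-force optimal matching over all permutations (test oracle)."""
    table = np.asarray(table)
    q = table.shape[0]
    best = max(
        sum(table[i, perm[i]] for i in range(q)) for perm in permutations(range(q))
    )
    return float(best / table.sum())


def ari(pred, ref) -> float:
    """Adjusted Rand index from the contingency table.

    (sum_ij C(n_ij,2) - E) / (max - E) with E the chance expectation
    sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2); 1 for identical partitions,
    ~0 under random labelling. Conventionally 1.0 when both partitions are
    trivial (the index is otherwise 0/0).
    """
    table = contingency_table(pred, ref)
    n = table.sum()
    sum_ij = comb(table, 2).sum()
    a = comb(table.sum(axis=1), 2).sum()
    b = comb(table.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = (a + b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class EvalVerdict:
    category: str
    ol: dict[int, float | None]
    ari: dict[int, float]
    n_domains_pred: int
    n_domains_refs: list[int]


def categorize(
    pred,
    refs,
    ol_threshold: float = 0.85,
    ari_threshold: float = 0.50,
    metric: str = "ol",
) -> EvalVerdict:
    """Classify a prediction against one or two references.

    correct: agreement (OL >= threshold, or ARI >= threshold in ARI mode)
    with ANY reference; overcut/undercut: more/fewer domains than every
    reference; boundary-inconsistency: domain count matches some reference
    but agreement is below threshold; other: anything else.
    """
    if isinstance(refs, (DomainAssignment, np.ndarray)):
        refs = [refs]
    if not refs:
        raise ValueError("at least one reference assignment is required")
    np_pred = (
        pred.n_domains
        if isinstance(pred, DomainAssignment)
        else len(np.unique(_labels_of(pred)))
    )
    ref_counts, ols, aris = [], {}, {}
    correct = False
    for k, ref in enumerate(refs):
        if isinstance(pred, DomainAssignment) and isinstance(ref, DomainAssignment):
            # references may leave residues unassigned: compare on the
            # residues covered by both
            p, r = labels_on_common_support(pred, ref)[:2]
        else:
            p, r = _labels_of(pred), _labels_of(ref)
        ref_counts.append(
            ref.n_domains if isinstance(ref, DomainAssignment)
            else len(np.unique(r))
        )
        aris[k] = ari(p, r)
        try:
            ols[k] = ol_score(p, r)
        except OLUndefined:
            ols[k] = None
        score = aris[k] if metric == "ari" else ols[k]
        threshold = ari_threshold if metric == "ari" else ol_threshold
        if score is not None and score >= threshold:
            correct = True

    if correct:
        category = "correct"
    elif all(np_pred > c for c in ref_counts):
        category = "overcut"
    elif all(np_pred < c for c in ref_counts):
        category = "undercut"
    elif any(np_pred == c for c in ref_counts):
        category = "boundary-inconsistency"
    else:
        category = "other"
    return EvalVerdict(
        category=category,
        ol=ols,
        ari=aris,
        n_domains_pred=np_pred,
        n_domains_refs=ref_counts,
    )
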