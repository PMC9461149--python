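"""Candidate partitionings and domain-count selection.

For increasing cluster counts m = 2, 3, ... the residues are clustered in
kernel feature space, then post-processed to respect protein structure:
split alpha-helices are re-unified (up to a maximum helix size MHS), short
segments are merged into their nearest neighbour segment (minimum segment
size MSS), and excessive fragmentation is reduced until the segment count is
at most SDR times the domain count. A candidate whose smallest domain falls
below the minimum domain size MDS is rejected and the loop stops. Among the
accepted candidates, the domain count maximizing the silhouette index over
hydrophobic residues (Kyte-Doolittle index > 2), measured in the
kernel-induced metric, is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .clustering import DEFAULT_RESTARTS, ClusterLabels, kernel_kmeans, spectral
from .contacts import ContactGraph
from .kernels import (
    DistanceMatrix,
    compute_kernel,
    default_bandwidth,
    kernel_to_distance,
)
from .structure import ProteinChain, hydrophobic_mask

logger = logging.getLogger(__name__)

#: Secondary-structure classes treated as alpha-helix for the merge step.
HELIX_CLASSES = ("H",)


class InfeasiblePartition(ValueError):
    """Post-processing cannot satisfy the segment/domain constraints."""


class SilhouetteUndefined(ValueError):
    """A cluster lacks the hydrophobic residues needed for the silhouette."""


@dataclass
class Params:
    """Structure-aware post-processing parameters.

    min_domain_size (MDS), max_helix_merge (MHS), min_segment_size (MSS) and
    max_segment_domain_ratio (SDR) with their standard defaults 27/30/27/1.5.
    """

    min_domain_size: int = 27
    max_helix_merge: int = 30
    min_segment_size: int = 27
    max_segment_domain_ratio: float = 1.5

    def __post_init__(self) -> None:
        if min(self.min_domain_size, self.max_helix_merge, self.min_segment_size) <= 0:
            raise ValueError("size parameters must be positive")
        if self.max_segment_domain_ratio <= 0:
            raise ValueError("max_segment_domain_ratio must be positive")


@dataclass
class Segment:
    """Contiguous residue run [b, e] (1-based, inclusive) with a cluster label."""

    b: int
    e: int
    label: int

    def __post_init__(self) -> None:
        if self.b > self.e:
            raise ValueError(f"segment start {self.b} after end {self.e}")

    @property
    def size(self) -> int:
        return self.e - self.b + 1


@dataclass
class SegmentList:
    """Ordered segments covering 1..n with no gaps; adjacent labels differ."""

    segments: list[Segment]

    @property
    def t(self) -> int:
        return len(self.segments)

    @property
    def n(self) -> int:
        return self.segments[-1].e

    def labels(self) -> np.ndarray:
        out = np.empty(self.n, dtype=int)
        for s in self.segments:
            out[s.b - 1 : s.e] = s.label
        return out

    def distinct_labels(self) -> set[int]:
        return {s.label for s in self.segments}

    def validate(self) -> None:
        pos = 1
        for prev, s in zip([None] + self.segments[:-1], self.segments):
            if s.b != pos:
                raise ValueError(f"segment gap/overlap at residue {pos}")
            if prev is not None and prev.label == s.label:
                raise ValueError(f"adjacent segments share label {s.label}")
            pos = s.e + 1


@dataclass
class CandidateClustering:
    """A post-processed labelling for one requested m, with its silhouette."""

    labels: np.ndarray
    m_requested: int
    m_effective: int
    silhouette: float
    segments: SegmentList


@dataclass
class DomainAssignment:
    """Final partitioning: each domain is a list of (possibly >1) segments."""

    domains: list[list[Segment]]
    source: str = "clustering"
    silhouette: float | None = None

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n(self) -> int:
        return sum(s.size for d in self.domains for s in d)

    def labels(self) -> np.ndarray:
        n_max = max(s.e for d in self.domains for s in d)
        out = np.zeros(n_max, dtype=int)
        for k, dom in enumerate(self.domains, start=1):
            for s in dom:
                out[s.b - 1 : s.e] = k
        if np.any(out == 0):
            raise ValueError(
                "assignment does not cover every residue; compare gapped "
                "assignments on their common residue support"
            )
        return out

    def residue_map(self) -> dict[int, int]:
        """1-based residue index -> 1-based domain index, covered residues only."""
        out: dict[int, int] = {}
        for k, dom in enumerate(self.domains, start=1):
            for s in dom:
                for r in range(s.b, s.e + 1):
                    out[r] = k
        return out

    def to_range_string(self) -> str:
        doms = sorted(self.domains, key=lambda d: min(s.b for s in d))
        return "|".join(
            ",".join(f"{s.b}-{s.e}" for s in sorted(d, key=lambda s: s.b))
            for d in doms
        )

    @classmethod
    def from_range_string(cls, text: str, source: str = "reference") -> "DomainAssignment":
        domains: list[list[Segment]] = []
        for k, dom_text in enumerate(text.strip().split("|"), start=1):
            segs = []
            for rng in dom_text.split(","):
                b, e = rng.strip().split("-")
                segs.append(Segment(b=int(b), e=int(e), label=k))
            domains.append(segs)
        return cls(domains=domains, source=source)

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, source: str = "clustering",
        silhouette: float | None = None,
    ) -> "DomainAssignment":
        seglist = to_segments(labels)
        by_label: dict[int, list[Segment]] = {}
        for s in seglist.segments:
            by_label.setdefault(s.label, []).append(s)
        doms = sorted(by_label.values(), key=lambda d: d[0].b)
        return cls(domains=doms, source=source, silhouette=silhouette)


def _label_array(labels) -> np.ndarray:
    if isinstance(labels, ClusterLabels):
        return np.asarray(labels.labels, dtype=int)
    return np.asarray(labels, dtype=int)


def merge_split_helices(labels, chain: ProteinChain, mhs: int) -> np.ndarray:
    """Re-unify alpha-helices split across clusters.

    Each maximal helix run of length <= mhs whose residues carry more than
    one label is relabelled to the run's majority label (ties broken by the
    label of the run's first residue); longer runs are left untouched.
    """
    lab = _label_array(labels).copy()
    ss = chain.ss_string()
    n = len(ss)
    i = 0
    while i < n:
        if ss[i] in HELIX_CLASSES:
            j = i
            while j + 1 < n and ss[j + 1] in HELIX_CLASSES:
                j += 1
            run = lab[i : j + 1]
            if (j - i + 1) <= mhs and len(np.unique(run)) > 1:
                values, counts = np.unique(run, return_counts=True)
                best = counts.max()
                tied = set(values[counts == best])
                majority = run[0] if run[0] in tied else values[counts == best][0]
                lab[i : j + 1] = majority
            i = j + 1
        else:
            i += 1
    return lab


def to_segments(labels) -> SegmentList:
    """Run-length encode a labelling into chain-ordered segments."""
    lab = _label_array(labels)
    if lab.size == 0:
        raise ValueError("empty labelling")
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(lab) + 1):
        if i == len(lab) or lab[i] != lab[start]:
            segments.append(Segment(b=start + 1, e=i, label=int(lab[start])))
            start = i
    return SegmentList(segments=segments)


def segment_distance(s1: Segment, s2: Segment, D: DistanceMatrix | np.ndarray) -> float:
    """Mean kernel-induced distance over all residue pairs of two segments."""
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D)
    return float(Dm[s1.b - 1 : s1.e, s2.b - 1 : s2.e].mean())


def merge_segment(
    S: SegmentList, i: int, D: DistanceMatrix | np.ndarray
) -> SegmentList:
    """Merge segment i (0-based) into its neighbourhood.

    If both neighbours share a label, all three coalesce under it; with
    different labels, the segment adopts the label of the nearer neighbour by
    mean inter-segment distance; a missing neighbour (chain start/end) forces
    merging with the other one. The result is re-normalized so adjacent equal
    labels coalesce.
    """
    if S.t < 2:
        raise InfeasiblePartition("single-segment list: nothing to merge into")
    if not (0 <= i < S.t):
        raise IndexError(f"segment index {i} out of range")
    seg = S.segments[i]
    pred = S.segments[i - 1] if i > 0 else None
    succ = S.segments[i + 1] if i < S.t - 1 else None
    if pred is not None and succ is not None:
        if pred.label == succ.label:
            new_label = pred.label
        else:
            d_pred = segment_distance(seg, pred, D)
            d_succ = segment_distance(seg, succ, D)
            new_label = pred.label if d_pred <= d_succ else succ.label
    elif pred is not None:
        new_label = pred.label
    else:
        new_label = succ.label

    lab = S.labels()
    lab[seg.b - 1 : seg.e] = new_label
    return to_segments(lab)


def remove_short_segments(
    S: SegmentList,
    D: DistanceMatrix | np.ndarray,
    mss: int,
    sdr: float,
    m: int,
) -> SegmentList:
    """Greedy removal of short and excessive segments.

    Repeatedly merges the currently shortest segment of size < mss (ties
    resolved by chain order) until none remain, then keeps merging the
    currently shortest segment while t/m > sdr. Raises
    :class:`InfeasiblePartition` if the list collapses below m distinct
    labels (the candidate for this m is then rejected).
    """
    cur = S

    def shortest_index(only_short: bool) -> int | None:
        best, best_size = None, None
        for idx, s in enumerate(cur.segments):
            if only_short and s.size >= mss:
                continue
            if best_size is None or s.size < best_size:
                best, best_size = idx, s.size
        return best

    while True:
        idx = shortest_index(only_short=True)
        if idx is None:
            break
        cur = merge_segment(cur, idx, D)
        if len(cur.distinct_labels()) < m:
            raise InfeasiblePartition(
                f"short-segment removal collapsed below {m} labels"
            )
    while cur.t / m > sdr:
        idx = shortest_index(only_short=False)
        cur = merge_segment(cur, idx, D)
        if len(cur.distinct_labels()) < m:
            raise InfeasiblePartition(
                f"segment-ratio enforcement collapsed below {m} labels"
            )
    return cur


def silhouette_score(
    labels, D: DistanceMatrix | np.ndarray, mask: np.ndarray
) -> float:
    """Mean silhouette over masked (hydrophobic) residues.

    a(i) is the mean distance from residue i to the other masked residues of
    its cluster; b(i) the smallest mean distance to the masked residues of
    any other cluster. Raises :class:`SilhouetteUndefined` when a cluster has
    fewer than two masked residues (a(i) would be undefined) or fewer than
    two clusters are present.
    """
    lab = _label_array(labels)
    mask = np.asarray(mask, dtype=bool)
    Dm = D.D if isinstance(D, DistanceMatrix) else np.asarray(D)
    midx = np.flatnonzero(mask)
    mlab = lab[midx]
    clusters = np.unique(lab)
    if len(clusters) < 2:
        raise SilhouetteUndefined("need at least 2 clusters")
    counts = {c: int(np.sum(mlab == c)) for c in clusters}
    bad = [c for c, k in counts.items() if k < 2]
    if bad:
        raise SilhouetteUndefined(
            f"clusters {bad} have fewer than 2 hydrophobic residues"
        )
    Dsub = Dm[np.ix_(midx, midx)]
    scores = np.empty(len(midx))
    for ii in range(len(midx)):
        same = mlab == mlab[ii]
        same_others = same.copy()
        same_others[ii] = False
        a = Dsub[ii, same_others].mean()
        b = min(Dsub[ii, mlab == c].mean() for c in clusters if c != mlab[ii])
        denom = max(a, b)
        scores[ii] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


@dataclass
class LoopReportEntry:
    m: int
    accepted: bool
    reason: str = ""
    silhouette: float | None = None
    m_effective: int | None = None


def candidate_loop(
    chain: ProteinChain,
    graph: ContactGraph,
    kernel_kind: str = "led",
    clusterer: str = "kernel-kmeans",
    eta: float | None = None,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    params: Params | None = None,
    m_bounds: tuple[int, int] | None = None,
    report: list[LoopReportEntry] | None = None,
) -> list[CandidateClustering]:
    """Generate post-processed candidate partitionings over increasing m.

    For each m: cluster, merge split helices, slice into segments, remove
    short/excessive segments, then accept the candidate if every domain
    (union of same-label segments) has at least min_domain_size residues.
    MDS rejection, label collapse or merge infeasibility stops the loop; a
    silhouette degeneracy only skips that m. An empty list is a valid
    outcome (the chain is then treated as single-domain).
    """
    params = params or Params()
    bw = default_bandwidth(kernel_kind, clusterer, chain.rg, eta)
    kernel = compute_kernel(graph, kernel_kind, bw)
    D = kernel_to_distance(kernel)
    mask = hydrophobic_mask(chain)

    n = chain.n
    hard_cap = n // params.min_domain_size
    if m_bounds is not None:
        lo, hi = m_bounds
        hi = min(hi, hard_cap) if hard_cap >= lo else lo - 1
    else:
        lo, hi = 2, hard_cap

    cluster_fn = kernel_kmeans if clusterer == "kernel-kmeans" else spectral
    candidates: list[CandidateClustering] = []
    for m in range(lo, hi + 1):
        entry = LoopReportEntry(m=m, accepted=False)
        if report is not None:
            report.append(entry)
        raw = cluster_fn(kernel, m, restarts=restarts, seed=seed)
        lab = merge_split_helices(raw, chain, params.max_helix_merge)
        seglist = to_segments(lab)
        if len(seglist.distinct_labels()) < m:
            entry.reason = "label collapse after helix merge"
            logger.info("m=%d rejected: %s", m, entry.reason)
            break
        try:
            seglist = remove_short_segments(
                seglist, D, params.min_segment_size,
                params.max_segment_domain_ratio, m,
            )
        except InfeasiblePartition as exc:
            entry.reason = str(exc)
            logger.info("m=%d rejected: %s", m, exc)
            break
        final = seglist.labels()
        dom_sizes = {
            c: int(np.sum(final == c)) for c in seglist.distinct_labels()
        }
        if min(dom_sizes.values()) < params.min_domain_size:
            entry.reason = (
                f"domain below minimum size {params.min_domain_size}: {dom_sizes}"
            )
            logger.info("m=%d rejected: %s", m, entry.reason)
            break
        try:
            sil = silhouette_score(final, D, mask)
        except SilhouetteUndefined as exc:
            entry.reason = f"silhouette undefined: {exc}"
            logger.info("m=%d skipped: %s", m, exc)
            continue
        entry.accepted = True
        entry.silhouette = sil
        entry.m_effective = len(dom_sizes)
        candidates.append(
            CandidateClustering(
                labels=final,
                m_requested=m,
                m_effective=len(dom_sizes),
                silhouette=sil,
                segments=seglist,
            )
        )
    return candidates


def select_assignment(
    candidates: list[CandidateClustering],
    verdict: str,
    n: int,
    forced_m: int | None = None,
) -> DomainAssignment:
    """Choose the final assignment from the candidates and the class verdict.

    'single' yields one chain-spanning domain; 'multi' takes the candidate
    with the highest silhouette (ties -> smaller m) or falls back to
    single-domain when no candidate survived; 'forced' requires the candidate
    with exactly forced_m effective domains.
    """
    if verdict == "single":
        return DomainAssignment(
            domains=[[Segment(b=1, e=n, label=1)]], source="classifier-single"
        )
    if verdict == "forced":
        for cand in candidates:
            if cand.m_effective == forced_m:
                return DomainAssignment.from_labels(
                    cand.labels, source="forced", silhouette=cand.silhouette
                )
        raise InfeasiblePartition(
            f"no feasible candidate with {forced_m} domains"
        )
    if verdict != "multi":
        raise ValueError(f"unknown verdict {verdict!r}")
    if not candidates:
        return DomainAssignment(
            domains=[[Segment(b=1, e=n, label=1)]], source="clustering"
        )
    best = max(candidates, key=lambda c: (c.silhouette, -c.m_requested))
    return DomainAssignment.from_labels(
        best.labels, source="clustering", silhouette=best.silhouette
    )
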