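"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written down a different path from the
package code: plain-Python loops, networkx cycle enumeration, and clique
search, so that agreement is meaningful.
"""

from __future__ import annotations

import math
from itertools import combinations

import networkx as nx
import numpy as np


def pair_energy_oracle(
    a_sites, b_sites, q_o=-0.834, q_h=0.417, k=332.0636, A=582000.0, C=595.0
) -> float:
    """9-term site-site Coulomb sum plus the O-O Lennard-Jones term.

    ``a_sites``/``b_sites`` are (3, 3) arrays in O, H, H order.
    """
    charges = [q_o, q_h, q_h]
    energy = 0.0
    for i in range(3):
        for j in range(3):
            r = math.dist(a_sites[i], b_sites[j])
            energy += k * charges[i] * charges[j] / r
    r_oo = math.dist(a_sites[0], b_sites[0])
    energy += A / r_oo**12 - C / r_oo**6
    return energy


def canonical_cycle(members) -> tuple[int, ...]:
    """Lexicographically smallest rotation/reflection, smallest member first."""
    members = list(members)
    n = len(members)
    best = None
    for seq in (members, list(reversed(members))):
        for shift in range(n):
            rotated = tuple(seq[(shift + i) % n] for i in range(n))
            if best is None or rotated < best:
                best = rotated
    return best


def chordless_cycles_oracle(edges, min_size=3, max_size=6) -> set[tuple[int, ...]]:
    """All chordless simple cycles of bounded size, canonicalized, via networkx."""
    g = nx.Graph()
    g.add_edges_from(edges)
    out = set()
    for cycle in nx.simple_cycles(g, length_bound=max_size):
        if len(cycle) < min_size:
            continue
        cycle_set = set(cycle)
        consecutive = {
            frozenset((cycle[i], cycle[(i + 1) % len(cycle)]))
            for i in range(len(cycle))
        }
        chord = any(
            frozenset((u, v)) not in consecutive
            for u, v in combinations(cycle_set, 2)
            if g.has_edge(u, v)
        )
        if not chord:
            out.add(canonical_cycle(cycle))
    return out


def center_of_mass_oracle(positions, masses) -> np.ndarray:
    """Plain-loop mass-weighted mean."""
    total = [0.0, 0.0, 0.0]
    msum = 0.0
    for pos, m in zip(positions, masses):
        for d in range(3):
            total[d] += m * pos[d]
        msum += m
    return np.array([t / msum for t in total])


def usr_moments_oracle(points) -> list[float]:
    """Direct moment summation for the 12-component shape descriptor."""
    pts = [tuple(map(float, p)) for p in points]
    n = len(pts)
    ctd = tuple(sum(p[d] for p in pts) / n for d in range(3))

    def dist(a, b):
        return math.dist(a, b)

    d_ctd = [dist(p, ctd) for p in pts]
    cst = pts[d_ctd.index(min(d_ctd))]
    fct = pts[d_ctd.index(max(d_ctd))]
    d_fct = [dist(p, fct) for p in pts]
    ftf = pts[d_fct.index(max(d_fct))]

    moments = []
    for ref in (ctd, cst, fct, ftf):
        ds = [dist(p, ref) for p in pts]
        mu1 = sum(ds) / n
        var = sum((d - mu1) ** 2 for d in ds) / n
        mu2 = math.sqrt(var)
        third = sum((d - mu1) ** 3 for d in ds) / n
        mu3 = math.copysign(abs(third) ** (1.0 / 3.0), third)
        moments.extend([mu1, mu2, mu3])
    return moments


def usr_similarity_oracle(m_q, m_i) -> float:
    """Direct evaluation of S = (1 + (1/12) sum |diff|)^-1."""
    total = sum(abs(a - b) for a, b in zip(m_q, m_i))
    return 1.0 / (1.0 + total / 12.0)


def _kabsch_residual(p, q) -> float:
    """Max residual after least-squares rigid superposition of q onto p."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = pc - r @ qc
    return float(np.max(np.linalg.norm(q @ r.T + t - p, axis=1)))


def site_match_oracle(pos1, elems1, pos2, elems2, tol) -> int:
    """Largest rigidly consistent same-element matching, by exhaustive search.

    Enumerates all correspondence subsets whose pairwise internal distances
    agree within 2*tol (a necessary condition for rigid matchability), then
    verifies candidates by least-squares superposition with max residual
    <= tol. Exponential; only for sites of ~10 atoms or fewer.
    """
    pos1 = [tuple(map(float, p)) for p in pos1]
    pos2 = [tuple(map(float, p)) for p in pos2]
    n1 = len(pos1)
    best = [0]

    def verify(corr) -> bool:
        if len(corr) < 3:
            return True
        p = [pos1[i] for i, _ in corr]
        q = [pos2[j] for _, j in corr]
        return _kabsch_residual(p, q) <= tol

    def extend(i, corr, used2):
        if len(corr) + (n1 - i) <= best[0]:
            return  # cannot beat current best
        if i == n1:
            if len(corr) > best[0] and verify(corr):
                best[0] = len(corr)
            return
        for j in range(len(pos2)):
            if j in used2 or elems1[i] != elems2[j]:
                continue
            ok = all(
                abs(math.dist(pos1[i], pos1[i2]) - math.dist(pos2[j], pos2[j2]))
                <= 2 * tol
                for i2, j2 in corr
            )
            if ok:
                extend(i + 1, corr + [(i, j)], used2 | {j})
        extend(i + 1, corr, used2)  # leave atom i unmatched

    extend(0, [], frozenset())
    return best[0]
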