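"""Shared fixtures: hand-built lineage trees and small simulated ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from linsel import CellRecord, LineageEnsemble


def build_tree_from_depths(
    depths: list[int],
    tau: float = 1.0,
    prefix: str = "c",
    t_offset: float = 0.0,
) -> dict[str, CellRecord]:
    """Build a full binary tree whose leaves sit at the given depths.

    The depth multiset must satisfy Kraft equality ``sum(2^-d) == 1`` (a full
    binary tree exists iff it does).  Leaves are assigned canonical binary
    codewords; internal node at depth k divides at ``t_offset + (k+1)*delta``
    with ``delta = tau/(max_depth+1)``, and every leaf survives to
    ``t_offset + tau``.  Cell ids are the codeword strings prefixed by
    ``prefix`` (root id is just ``prefix``).
    """
    depths = sorted(depths)
    assert abs(sum(2.0**-d for d in depths) - 1.0) < 1e-12, "Kraft sum must be 1"
    codes: list[str] = []
    code = 0
    for i, d in enumerate(depths):
        codes.append(format(code, f"0{d}b") if d else "")
        if i + 1 < len(depths):
            code = (code + 1) << (depths[i + 1] - d)
    delta = tau / (max(depths) + 1)
    nodes = {c for c in codes}
    for c in codes:
        for k in range(len(c)):
            nodes.add(c[:k])
    records = {}
    leaf_set = set(codes)
    for c in sorted(nodes):
        k = len(c)
        cid = prefix + c
        is_leaf = c in leaf_set
        records[cid] = CellRecord(
            cell_id=cid,
            parent_id=(prefix + c[:-1]) if c else None,
            birth_time=t_offset + k * delta,
            end_time=t_offset + (tau if is_leaf else (k + 1) * delta),
            fate="extant" if is_leaf else "divided",
        )
    return records


@pytest.fixture
def fig2_tree() -> LineageEnsemble:
    """A 13-leaf division tree containing lineages with D = 3 and D = 5.

    Synthetic stand-in: a full binary tree with leaf depths
    {2 x1, 3 x3, 4 x3, 5 x6} (Kraft sum exactly 1), reproducing the
    worked-example quantities N(t1) = 13, pi_cl = 1/8 at D = 3 and 1/32 at
    D = 5, and pi_rs = 1/13 for every lineage.
    """
    depths = [2] + [3] * 3 + [4] * 3 + [5] * 6
    return LineageEnsemble(build_tree_from_depths(depths, tau=250 / 60), t0=0.0)


@pytest.fixture
def balanced_tree() -> LineageEnsemble:
    """A tree where every lineage has the same division count (D = 2)."""
    return LineageEnsemble(build_tree_from_depths([2, 2, 2, 2], tau=1.0), t0=0.0)


def two_tree_records() -> dict[str, CellRecord]:
    """Two trees over tau = 1 h: A divides once (both leaves), B never does."""
    recs = build_tree_from_depths([1, 1], tau=1.0, prefix="A")
    recs.update(build_tree_from_depths([0], tau=1.0, prefix="B"))
    return recs


@pytest.fixture
def two_tree_ensemble() -> LineageEnsemble:
    return LineageEnsemble(two_tree_records(), t0=0.0, t1=1.0)


def make_ou_chain(
    n_frames: int,
    dt_h: float,
    mu: float,
    sigma2: float,
    gamma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Reference stationary OU chain of ln y (independent oracle for tests)."""
    a = np.exp(-gamma * dt_h)
    z = np.empty(n_frames)
    z[0] = mu + np.sqrt(sigma2) * rng.standard_normal()
    innov = np.sqrt(sigma2 * (1 - a * a)) * rng.standard_normal(n_frames - 1)
    for i in range(1, n_frames):
        z[i] = mu + a * (z[i - 1] - mu) + innov[i - 1]
    return z
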