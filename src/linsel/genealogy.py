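"""Data model and I/O for annotated single-cell lineage trees.

A tracked population is a forest of rooted binary division trees observed
over a time window ``[t0, t1]``.  Every cell alive at ``t1`` terminates one
*lineage* — the root-to-leaf path through the tree — and each lineage ``i``
carries a division count ``D_i`` (number of divisions on the path inside the
window).  Two natural probabilities attach to a lineage:

* the **chronological** probability ``2^(-D_i) / N(t0)`` of reaching it by
  descending the tree forward in time, picking a daughter uniformly at each
  division, and
* the **retrospective** probability ``1 / N(t1)`` of picking it uniformly
  among the ancestries of surviving cells.

The mismatch between the two is what all downstream selection statistics
are built on.  Internal time unit is hours throughout.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("linsel")

LN2 = float(np.log(2.0))

#: allowed values of :attr:`CellRecord.fate`
FATES = ("divided", "extant", "censored")

_TIME_UNIT_TO_HOURS = {"h": 1.0, "hours": 1.0, "min": 1.0 / 60.0, "minutes": 1.0 / 60.0}

# tolerance (h) when matching division times between mother and daughters
_TIME_TOL = 1e-9


class GenealogyError(ValueError):
    """Raised when a cell table violates the lineage-tree invariants."""


@dataclass
class CellRecord:
    """One tracked cell: genealogical links, lifetime and per-frame samples.

    ``samples`` is a float array of shape ``(k, 3)`` with columns
    ``(time, size v, fluorescence c)`` at the fixed frame interval of the
    measurement.  Sample times lie within ``[birth_time, end_time]`` and
    sizes are strictly positive.
    """

    cell_id: str
    parent_id: str | None
    birth_time: float
    end_time: float
    fate: str = "extant"
    samples: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def validate(self) -> None:
        if self.fate not in FATES:
            raise GenealogyError(f"cell {self.cell_id}: unknown fate {self.fate!r}")
        if self.fate == "divided":
            if not self.birth_time < self.end_time:
                raise GenealogyError(
                    f"cell {self.cell_id}: birth_time must precede end_time"
                )
        elif self.birth_time > self.end_time:
            raise GenealogyError(
                f"cell {self.cell_id}: birth_time must not exceed end_time"
            )
        s = np.asarray(self.samples, dtype=float)
        if s.size:
            if s.ndim != 2 or s.shape[1] != 3:
                raise GenealogyError(f"cell {self.cell_id}: samples must be (k, 3)")
            if np.any(np.diff(s[:, 0]) <= 0):
                raise GenealogyError(f"cell {self.cell_id}: sample times not increasing")
            if (s[0, 0] < self.birth_time - _TIME_TOL) or (
                s[-1, 0] > self.end_time + _TIME_TOL
            ):
                raise GenealogyError(
                    f"cell {self.cell_id}: sample times outside [birth, end]"
                )
            if np.any(s[:, 1] <= 0):
                raise GenealogyError(f"cell {self.cell_id}: non-positive cell size")


@dataclass
class Lineage:
    """One root-to-leaf path across the observation window."""

    leaf_id: str
    path: tuple[str, ...]
    D: int
    w_cl: float
    w_rs: float
    phenotypes: dict[str, float] = field(default_factory=dict)


class LineageEnsemble:
    """A forest of cell-lineage trees observed over ``[t0, t1]``.

    Parameters
    ----------
    records
        Mapping cell_id -> :class:`CellRecord` for every tracked cell.
    t0, t1
        Window bounds in hours.  Defaults: earliest birth / latest end.

    The ensemble is validated on construction: parent links must resolve and
    be acyclic, divided cells must have exactly two daughters born at the
    mother's end time, and each file-level root must be born at or before
    ``t0``.  Cells that vanish before ``t1`` without dividing are flagged
    ``censored``; their branches are excluded from lineage enumeration and
    counted in :attr:`n_censored`.
    """

    def __init__(
        self,
        records: Mapping[str, CellRecord],
        t0: float | None = None,
        t1: float | None = None,
    ):
        if not records:
            raise GenealogyError("empty cell table")
        self.records: dict[str, CellRecord] = dict(records)
        self.children: dict[str, list[str]] = {cid: [] for cid in self.records}
        self.roots: list[str] = []
        for cid, rec in self.records.items():
            rec.validate()
            if rec.parent_id is None:
                self.roots.append(cid)
            else:
                if rec.parent_id not in self.records:
                    raise GenealogyError(
                        f"cell {cid}: parent {rec.parent_id!r} not in table"
                    )
                self.children[rec.parent_id].append(cid)
        if not self.roots:
            raise GenealogyError("no root cells (cyclic parent links?)")
        self._check_acyclic()
        self._check_divisions()

        times = [r.birth_time for r in self.records.values()]
        ends = [r.end_time for r in self.records.values()]
        self.t0 = float(min(times)) if t0 is None else float(t0)
        self.t1 = float(max(ends)) if t1 is None else float(t1)
        if not self.t1 > self.t0:
            raise GenealogyError("window requires t0 < t1")

        for rid in self.roots:
            if self.records[rid].birth_time > self.t0 + _TIME_TOL:
                raise GenealogyError(
                    f"tree root {rid} born after t0={self.t0}; "
                    "trees must span the whole window"
                )

        self._flag_censored()
        self.window_roots: list[str] = sorted(
            (
                cid
                for cid, r in self.records.items()
                if r.birth_time <= self.t0 + _TIME_TOL and r.end_time > self.t0 + _TIME_TOL
            ),
        )
        if not self.window_roots:
            raise GenealogyError("no cells alive at t0")
        self.n_censored = sum(1 for r in self.records.values() if r.fate == "censored")
        if self.n_censored:
            logger.warning("%d censored cell(s) excluded from lineage weights", self.n_censored)

    # -- construction helpers -------------------------------------------------

    def _check_acyclic(self) -> None:
        seen: set[str] = set()
        for cid in self.records:
            chain = []
            cur: str | None = cid
            while cur is not None and cur not in seen:
                if cur in chain:
                    raise GenealogyError(f"cyclic parent links involving {cur}")
                chain.append(cur)
                cur = self.records[cur].parent_id
            seen.update(chain)

    def _check_divisions(self) -> None:
        for cid, rec in self.records.items():
            kids = self.children[cid]
            if rec.fate == "divided":
                if len(kids) != 2:
                    raise GenealogyError(
                        f"cell {cid} marked divided has {len(kids)} children (need 2)"
                    )
                for k in kids:
                    if abs(self.records[k].birth_time - rec.end_time) > 1e-6:
                        raise GenealogyError(
                            f"daughter {k} not born at mother {cid}'s division time"
                        )
            elif kids:
                raise GenealogyError(f"non-divided cell {cid} has children")

    def _flag_censored(self) -> None:
        for cid, rec in self.records.items():
            if (
                rec.fate == "extant"
                and not self.children[cid]
                and rec.end_time < self.t1 - _TIME_TOL
            ):
                logger.warning("cell %s lost before t1; flagged censored", cid)
                rec.fate = "censored"

    # -- window geometry ------------------------------------------------------

    @property
    def tau(self) -> float:
        """Window duration ``t1 - t0`` in hours."""
        return self.t1 - self.t0

    def _is_window_leaf(self, cid: str) -> bool:
        rec = self.records[cid]
        if rec.fate == "censored" or rec.birth_time > self.t1 + _TIME_TOL:
            return False
        if rec.fate == "divided":
            return rec.end_time > self.t1 + _TIME_TOL
        return rec.end_time >= self.t1 - _TIME_TOL

    @property
    def N0(self) -> int:
        """Number of cells alive at ``t0`` (the window roots)."""
        return len(self.window_roots)

    @property
    def N1(self) -> int:
        """Number of cells alive at ``t1`` (= number of surviving lineages)."""
        return sum(1 for cid in self.records if self._is_window_leaf(cid))

    # -- iteration ------------------------------------------------------------

    def paths(self) -> Iterable[tuple[str, ...]]:
        """Yield every window-root -> window-leaf path, in deterministic order."""
        for root in self.window_roots:
            stack: list[tuple[str, tuple[str, ...]]] = [(root, (root,))]
            while stack:
                cid, path = stack.pop()
                if self._is_window_leaf(cid):
                    yield path
                    continue
                kids = sorted(self.children[cid], reverse=True)
                for k in kids:
                    stack.append((k, path + (k,)))

    def division_count(self, path: tuple[str, ...]) -> int:
        """Divisions on a path with division time in the half-open ``(t0, t1]``."""
        d = 0
        for cid in path:
            rec = self.records[cid]
            if (
                rec.fate == "divided"
                and self.t0 + _TIME_TOL < rec.end_time <= self.t1 + _TIME_TOL
            ):
                d += 1
        return d

    # -- export ---------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick serialization of the file-level trees (one per line).

        Branch lengths are cell lifetimes (h) and labels are cell ids.
        Per-frame samples are not round-tripped.
        """
        import dendropy

        out = []
        for root in sorted(self.roots):
            tree = dendropy.Tree()
            nodes = {root: tree.seed_node}
            tree.seed_node.taxon = None
            order = [root]
            i = 0
            while i < len(order):
                cid = order[i]
                i += 1
                node = nodes[cid]
                rec = self.records[cid]
                node.label = cid
                node.edge.length = rec.end_time - rec.birth_time
                for k in sorted(self.children[cid]):
                    nodes[k] = node.new_child()
                    order.append(k)
            out.append(
                tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    suppress_leaf_node_labels=False,
                ).strip()
            )
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Core lineage statistics


def enumerate_lineages(ensemble: LineageEnsemble) -> list[Lineage]:
    """One :class:`Lineage` per cell alive at ``t1``, with both weights set.

    Chronological weight ``w_cl = 2^(-D) / N0``; retrospective weight
    ``w_rs = 1 / N1``; pooling across trees uses the global ``N0`` and ``N1``.
    Censored branches are excluded (reported via ``ensemble.n_censored``).
    """
    n1 = ensemble.N1
    if n1 == 0:
        raise GenealogyError("no lineage survives to t1")
    n0 = ensemble.N0
    lineages = []
    for path in ensemble.paths():
        d = ensemble.division_count(path)
        lineages.append(
            Lineage(
                leaf_id=path[-1],
                path=path,
                D=d,
                w_cl=2.0 ** (-d) / n0,
                w_rs=1.0 / n1,
            )
        )
    return lineages


def growth_rate(ensemble: LineageEnsemble) -> float:
    """Population growth rate ``Λ = ln(N1/N0) / τ`` in 1/h."""
    return float(np.log(ensemble.N1 / ensemble.N0) / ensemble.tau)


def lineage_fitness(D: int | np.ndarray, tau: float) -> float | np.ndarray:
    """Lineage fitness ``h̃(D) = D ln2 / τ`` (1/h).

    The exponential amplification rate implied by ``D`` divisions in a window
    of length ``tau``; lineages with ``h̃(D) > Λ`` are over-represented
    retrospectively.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    return np.asarray(D) * LN2 / tau if np.ndim(D) else D * LN2 / tau


# ---------------------------------------------------------------------------
# Tabular I/O

_CELL_COLS = ["cell_id", "parent_id", "birth_time", "end_time", "fate"]
_SAMPLE_COLS = ["cell_id", "time", "size", "fluorescence"]


def read_cell_table(
    path: str | io.TextIOBase,
    samples_path: str | io.TextIOBase | None = None,
    t0: float | None = None,
    t1: float | None = None,
    time_unit: str = "h",
) -> LineageEnsemble:
    """Read the tab-separated cell-record table (+ optional samples table).

    The cell table has columns ``cell_id parent_id birth_time end_time fate``
    (``parent_id`` empty for roots); the long-format samples table has
    ``cell_id time size fluorescence``.  ``time_unit`` may be ``"h"`` or
    ``"min"``; all times are converted to hours on read, as are ``t0``/``t1``
    when given.
    """
    scale = _TIME_UNIT_TO_HOURS.get(time_unit)
    if scale is None:
        raise ValueError(f"unknown time unit {time_unit!r}")
    cells = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "parent_id": str})
    missing = [c for c in _CELL_COLS if c not in cells.columns]
    if missing:
        raise GenealogyError(f"cell table missing columns {missing}")

    sample_map: dict[str, np.ndarray] = {}
    if samples_path is not None:
        samp = pd.read_csv(samples_path, sep="\t", dtype={"cell_id": str})
        missing = [c for c in _SAMPLE_COLS if c not in samp.columns]
        if missing:
            raise GenealogyError(f"samples table missing columns {missing}")
        for cid, grp in samp.groupby("cell_id", sort=False):
            arr = grp[["time", "size", "fluorescence"]].to_numpy(dtype=float)
            arr = arr[np.argsort(arr[:, 0], kind="stable")]
            arr[:, 0] *= scale
            sample_map[str(cid)] = arr

    records: dict[str, CellRecord] = {}
    for row in cells.itertuples(index=False):
        cid = str(row.cell_id)
        if cid in records:
            raise GenealogyError(f"duplicate cell_id {cid}")
        pid = None if pd.isna(row.parent_id) or row.parent_id == "" else str(row.parent_id)
        records[cid] = CellRecord(
            cell_id=cid,
            parent_id=pid,
            birth_time=float(row.birth_time) * scale,
            end_time=float(row.end_time) * scale,
            fate=str(row.fate),
            samples=sample_map.get(cid, np.empty((0, 3))),
        )
    return LineageEnsemble(
        records,
        t0=None if t0 is None else t0 * scale,
        t1=None if t1 is None else t1 * scale,
    )


def write_cell_table(
    ensemble: LineageEnsemble,
    cells_path: str,
    samples_path: str | None = None,
    time_unit: str = "h",
) -> None:
    """Write an ensemble back to the tabular format (times in ``time_unit``)."""
    scale = 1.0 / _TIME_UNIT_TO_HOURS[time_unit]
    rows = []
    srows = []
    for cid in sorted(ensemble.records):
        rec = ensemble.records[cid]
        rows.append(
            {
                "cell_id": rec.cell_id,
                "parent_id": "" if rec.parent_id is None else rec.parent_id,
                "birth_time": rec.birth_time * scale,
                "end_time": rec.end_time * scale,
                "fate": rec.fate,
            }
        )
        for t, v, c in np.asarray(rec.samples, dtype=float):
            srows.append(
                {"cell_id": cid, "time": t * scale, "size": v, "fluorescence": c}
            )
    pd.DataFrame(rows, columns=_CELL_COLS).to_csv(cells_path, sep="\t", index=False)
    if samples_path is not None:
        pd.DataFrame(srows, columns=_SAMPLE_COLS).to_csv(
            samples_path, sep="\t", index=False
        )
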