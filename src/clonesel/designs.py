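"""Field-trial layouts for early-stage clonal selection.

Two unreplicated/partially replicated designs are supported:

* **ABD** — augmented block design: every check cultivar appears exactly
  once in every block, every test clone appears exactly once overall.
* **P-REP** — partially replicated design: every entry appears at least
  once; a subset of clones is duplicated (in distinct blocks) so that a
  target fraction ``p_N`` of plots carries second replicates.

``p_N = (N - N_treat) / N`` where ``N`` is the number of plots and
``N_treat`` the number of distinct treatments (clones + checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "InvalidDesignError",
    "Entry",
    "TrialDesign",
    "make_abd_design",
    "make_prep_design",
]

SEASONS = ("WHS", "MHS", "HHS")


class InvalidDesignError(ValueError):
    """Raised when a requested layout cannot be constructed."""


@dataclass(frozen=True)
class Entry:
    """One treatment in the entry catalog: a test clone or a check cultivar."""

    entry_id: str
    kind: str  # "clone" | "check"
    family_id: str | None = None  # clones only

    def __post_init__(self) -> None:
        if self.kind not in ("clone", "check"):
            raise ValueError(f"unknown entry kind {self.kind!r}")
        if self.kind == "clone" and self.family_id is None:
            raise ValueError(f"clone {self.entry_id!r} has no family")
        if self.kind == "check" and self.family_id is not None:
            raise ValueError(f"check {self.entry_id!r} must not carry a family")


@dataclass
class TrialDesign:
    """Plot/block/entry layout of a single trial.

    ``plots`` is an ordered list of ``(plot_id, block_id, entry_id)``;
    ``entries`` maps entry_id to its :class:`Entry`.
    """

    trial_id: str
    season: str
    design_kind: str  # "ABD" | "PREP"
    plots: list[tuple[str, str, str]]
    entries: dict[str, Entry] = field(repr=False)

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.design_kind not in ("ABD", "PREP"):
            raise ValueError(f"design_kind must be ABD or PREP, got {self.design_kind!r}")
        for plot_id, _block, entry_id in self.plots:
            if entry_id not in self.entries:
                raise InvalidDesignError(
                    f"plot {plot_id!r} references uncataloged entry {entry_id!r}"
                )

    # -- counts ---------------------------------------------------------
    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_blocks(self) -> int:
        return len({b for _, b, _ in self.plots})

    @property
    def clones(self) -> list[str]:
        return sorted(e.entry_id for e in self.entries.values() if e.kind == "clone")

    @property
    def checks(self) -> list[str]:
        return sorted(e.entry_id for e in self.entries.values() if e.kind == "check")

    @property
    def families(self) -> list[str]:
        return sorted({e.family_id for e in self.entries.values() if e.kind == "clone"})

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def n_checks(self) -> int:
        return len(self.checks)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_treat(self) -> int:
        return self.n_clones + self.n_checks

    def family_of(self, entry_id: str) -> str | None:
        return self.entries[entry_id].family_id

    def p_n(self) -> float:
        """Fraction of plots occupied by replicates beyond one per treatment."""
        n = self.n_plots
        return (n - self.n_treat) / n

    def fieldbook(self):
        """The layout as a plain table (plot order preserved)."""
        import pandas as pd

        rows = []
        for plot_id, block_id, entry_id in self.plots:
            e = self.entries[entry_id]
            rows.append(
                {
                    "plot": plot_id,
                    "block": block_id,
                    "entry": entry_id,
                    "family": e.family_id if e.family_id is not None else "",
                    "is_check": int(e.kind == "check"),
                }
            )
        return pd.DataFrame(rows)


def _build_entries(
    families: Mapping[str, int], checks: Sequence[str]
) -> tuple[dict[str, Entry], list[str]]:
    if not checks:
        raise InvalidDesignError("at least one check is required")
    if not families or any(c <= 0 for c in families.values()):
        raise InvalidDesignError("every family must contribute at least one clone")
    entries: dict[str, Entry] = {}
    clone_ids: list[str] = []
    for fam in sorted(families):
        for k in range(families[fam]):
            cid = f"{fam}.c{k + 1:03d}"
            entries[cid] = Entry(cid, "clone", fam)
            clone_ids.append(cid)
    for chk in checks:
        if chk in entries:
            raise InvalidDesignError(f"check id {chk!r} collides with a clone id")
        entries[chk] = Entry(chk, "check")
    return entries, clone_ids


def make_abd_design(
    n_blocks: int,
    families: Mapping[str, int],
    checks: Sequence[str],
    seed: int = 0,
    trial_id: str = "T1",
    season: str = "WHS",
) -> TrialDesign:
    """Lay out an augmented block design.

    Clones are divided as evenly as possible across the ``n_blocks`` blocks
    (remainders go to the first blocks); each check is replicated once per
    block.  Clone-to-block assignment is randomized under ``seed``.
    """
    if n_blocks < 2:
        raise InvalidDesignError("ABD needs at least 2 blocks")
    entries, clone_ids = _build_entries(families, checks)
    rng = np.random.default_rng(seed)
    order = [clone_ids[i] for i in rng.permutation(len(clone_ids))]

    n_clones = len(clone_ids)
    base, rem = divmod(n_clones, n_blocks)
    plots: list[tuple[str, str, str]] = []
    pos = 0
    plot_no = 0
    for b in range(n_blocks):
        block_id = f"B{b + 1:02d}"
        take = base + (1 if b < rem else 0)
        block_entries = list(order[pos : pos + take]) + list(checks)
        pos += take
        for eid in block_entries:
            plot_no += 1
            plots.append((f"P{plot_no:04d}", block_id, eid))
    return TrialDesign(trial_id, season, "ABD", plots, entries)


def make_prep_design(
    n_blocks: int,
    families: Mapping[str, int],
    checks: Sequence[str],
    target_p_n: float,
    seed: int = 0,
    trial_id: str = "T1",
    season: str = "WHS",
) -> TrialDesign:
    """Lay out a partially replicated (p-rep) design.

    Every entry appears once; ``d`` clones (chosen uniformly at random
    under ``seed``) are duplicated so the realized ``p_N = d / (N_treat + d)``
    is the closest achievable to ``target_p_n``.  The two replicates of a
    duplicated clone are always placed in distinct blocks.
    """
    if not (0 < target_p_n < 0.5):
        raise InvalidDesignError("target_p_n must lie in (0, 0.5)")
    if n_blocks < 2:
        raise InvalidDesignError("P-REP needs at least 2 blocks")
    entries, clone_ids = _build_entries(families, checks)
    n_treat = len(entries)

    # d duplicates give p_N = d/(n_treat + d); invert and round to nearest
    d_exact = target_p_n * n_treat / (1.0 - target_p_n)
    best_d = min(
        (int(np.floor(d_exact)), int(np.ceil(d_exact))),
        key=lambda d: abs(d / (n_treat + d) - target_p_n) if d >= 0 else np.inf,
    )
    if best_d < 1:
        raise InvalidDesignError("target_p_n too small: no clone would be duplicated")
    if best_d > len(clone_ids):
        raise InvalidDesignError("target_p_n unreachable: not enough clones to duplicate")

    rng = np.random.default_rng(seed)
    dup = set(rng.choice(np.asarray(clone_ids, dtype=object), size=best_d, replace=False))

    n_plots = n_treat + best_d
    capacity = _block_capacities(n_plots, n_blocks)

    # Greedy fill: place each entry's replicate(s) into the least-filled
    # block(s) not already holding that entry.
    fill = [0] * n_blocks
    assignment: list[list[str]] = [[] for _ in range(n_blocks)]
    work = [(eid, 2 if eid in dup else 1) for eid in entries]
    work = [work[i] for i in rng.permutation(len(work))]
    work.sort(key=lambda t: -t[1])  # duplicated entries first (harder to place)
    for eid, reps in work:
        chosen: list[int] = []
        order = sorted(range(n_blocks), key=lambda b: (fill[b], rng.random()))
        for b in order:
            if fill[b] < capacity[b] and b not in chosen:
                chosen.append(b)
            if len(chosen) == reps:
                break
        if len(chosen) < reps:
            raise InvalidDesignError("block capacity insufficient for replicate placement")
        for b in chosen:
            assignment[b].append(eid)
            fill[b] += 1

    plots: list[tuple[str, str, str]] = []
    plot_no = 0
    for b in range(n_blocks):
        block_id = f"B{b + 1:02d}"
        for eid in assignment[b]:
            plot_no += 1
            plots.append((f"P{plot_no:04d}", block_id, eid))
    return TrialDesign(trial_id, season, "PREP", plots, entries)


def _block_capacities(n_plots: int, n_blocks: int) -> list[int]:
    base, rem = divmod(n_plots, n_blocks)
    return [base + (1 if b < rem else 0) for b in range(n_blocks)]


def split_families(n_clones: int, n_families: int, prefix: str = "F") -> dict[str, int]:
    """Divide ``n_clones`` clones over ``n_families`` families as evenly as possible."""
    if n_families < 1 or n_clones < n_families:
        raise InvalidDesignError("need at least one clone per family")
    base, rem = divmod(n_clones, n_families)
    return {
        f"{prefix}{i + 1:02d}": base + (1 if i < rem else 0) for i in range(n_families)
    }
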