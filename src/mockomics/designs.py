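"""Categorical strain designs and their mechanistic production readout.

A *design* assigns each target reaction one of three categories:

    0 — KO: flux fixed to zero,
    1 — NoMod: reaction left unmodified,
    2 — UP: flux fixed to twice its wild-type value at the same time point.

With ``d`` target reactions the design space has ``3^d`` members; the all-1
vector is the canonical wild type.  An initial training batch is drawn by
Latin-hypercube sampling on ``[0,1]^d`` (each coordinate ``x`` mapped to the
category ``floor(3x)``, clipped to 2 at ``x = 1``), deduplicated, and topped
up with the wild-type design — e.g. 95 sampled designs plus WT for one
96-well plate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .batch import BatchTimeSeries, run_designed_batch
from .model import BoundOverride, FluxState, MetabolicModel

KO, NOMOD, UP = 0, 1, 2
CATEGORIES = (KO, NOMOD, UP)


@dataclass
class Design:
    """One strain design: ordered reaction → category map plus a line name."""

    categories: dict[str, int]
    label: str = ""

    def __post_init__(self) -> None:
        bad = {r: c for r, c in self.categories.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"categories outside {{0,1,2}}: {bad}")

    @property
    def reactions(self) -> list[str]:
        return list(self.categories)

    @property
    def is_wt(self) -> bool:
        return all(c == NOMOD for c in self.categories.values())

    def key(self) -> tuple[int, ...]:
        """Canonical category tuple, in the design's reaction order."""
        return tuple(self.categories.values())

    def validate(self, model: MetabolicModel) -> None:
        for rxn in self.categories:
            if rxn not in model.reaction_ids:
                raise KeyError(f"design targets unknown reaction {rxn!r}")


@dataclass
class DesignBatch:
    """A set of pairwise-distinct designs, optionally containing the WT."""

    designs: list[Design]
    includes_wt: bool = False

    def __post_init__(self) -> None:
        keys = [d.key() for d in self.designs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate category vectors in design batch")
        n_wt = sum(d.is_wt for d in self.designs)
        if self.includes_wt and n_wt != 1:
            raise ValueError(f"expected exactly one WT design, found {n_wt}")

    def __len__(self) -> int:
        return len(self.designs)

    def __iter__(self):
        return iter(self.designs)


def design_space_size(n_reactions: int, n_categories: int = 3) -> int:
    """Number of possible designs: ``n_categories ** n_reactions`` (exact int)."""
    if n_reactions < 1 or n_categories < 1:
        raise ValueError("both arguments must be >= 1")
    return n_categories**n_reactions


def category_from_unit_interval(x: float) -> int:
    """Map a coordinate in [0, 1] to a category: ``floor(3x)`` clipped to 2."""
    return min(int(np.floor(3.0 * x)), UP)


def enumerate_design_space(reactions: list[str]) -> "itertools.product":
    """All category vectors over the targets, in lexicographic order."""
    return itertools.product(CATEGORIES, repeat=len(reactions))


def latin_hypercube_designs(
    n: int, reactions: list[str], rng_seed: int = 0, max_redraws: int = 1000
) -> DesignBatch:
    """Draw ``n − 1`` Latin-hypercube designs and append the wild type.

    The hypercube draw stratifies each coordinate of ``[0,1]^d``; coordinates
    map to categories by ``floor(3x)``.  Collisions (between sampled rows, or
    with the WT vector) are resolved by redrawing only the collided rows,
    which preserves the stratification of the survivors.
    """
    d = len(reactions)
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > design_space_size(d):
        raise ValueError(f"n={n} exceeds the design space size 3^{d}")

    wt_key = tuple([NOMOD] * d)
    sampler = qmc.LatinHypercube(d=d, seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    rows: list[tuple[int, ...]] = []
    if n > 1:
        points = sampler.random(n - 1)
        rows = [
            tuple(category_from_unit_interval(x) for x in point) for point in points
        ]
        seen: set[tuple[int, ...]] = {wt_key}
        redraws = 0
        for i, row in enumerate(rows):
            while rows[i] in seen:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError(
                        "could not deduplicate designs within "
                        f"{max_redraws} redraws"
                    )
                rows[i] = tuple(
                    category_from_unit_interval(x) for x in rng.random(d)
                )
            seen.add(rows[i])

    designs = [
        Design(dict(zip(reactions, row)), label=f"BE{i + 1}")
        for i, row in enumerate(rows)
    ]
    designs.append(Design({r: NOMOD for r in reactions}, label="WT"))
    return DesignBatch(designs=designs, includes_wt=True)


def design_to_overrides(design: Design, wt_flux: FluxState) -> BoundOverride:
    """Translate a design into MOMA bound overrides at one time point.

    KO fixes the flux to 0; UP fixes it to twice the wild-type flux at the
    same time point (a no-op equality 0 = 2·0 when the wild-type flux is
    zero); NoMod leaves the reaction free.
    """
    overrides = BoundOverride()
    for rxn, cat in design.categories.items():
        if cat == KO:
            overrides[rxn] = (0.0, 0.0)
        elif cat == UP:
            target = 2.0 * wt_flux.fluxes[rxn]
            overrides[rxn] = (target, target)
    return overrides


def simulate_design_production(
    model: MetabolicModel,
    wt_series: BatchTimeSeries,
    design: Design,
    target_metabolite: str,
    overlay_wt: bool = False,
) -> float:
    """Final extracellular target concentration (mM) of an engineered strain.

    Runs the MOMA batch simulation with the design's overrides recomputed
    from the wild-type flux vector of each time point; a lethal design (MOMA
    infeasible at the start) reads out as 0.
    """
    design.validate(model)
    if target_metabolite not in model.exchange_map:
        raise KeyError(f"{target_metabolite!r} has no exchange reaction")
    overrides = [
        design_to_overrides(design, wt_series.fluxes[k])
        for k in range(len(wt_series))
    ]
    series = run_designed_batch(model, wt_series, overrides, overlay_wt=overlay_wt)
    if series.lethal and series.lethal_from == 0:
        return 0.0
    return series.final_concentration(target_metabolite)


# -- design CSV dialect ------------------------------------------------------

LINE_NAME_COLUMN = "Line Name"


def designs_to_frame(batch: DesignBatch) -> pd.DataFrame:
    """One row per design: line name plus one 0/1/2 column per target."""
    if not batch.designs:
        return pd.DataFrame(columns=[LINE_NAME_COLUMN])
    reactions = batch.designs[0].reactions
    rows = []
    for design in batch:
        row = {LINE_NAME_COLUMN: design.label}
        row.update(design.categories)
        rows.append(row)
    return pd.DataFrame(rows, columns=[LINE_NAME_COLUMN, *reactions])


def write_designs_csv(batch: DesignBatch, path) -> None:
    designs_to_frame(batch).to_csv(path, index=False)


def read_designs_csv(path) -> DesignBatch:
    df = pd.read_csv(path)
    if LINE_NAME_COLUMN not in df.columns:
        raise ValueError(f"designs CSV lacks a {LINE_NAME_COLUMN!r} column")
    reactions = [c for c in df.columns if c != LINE_NAME_COLUMN]
    designs = [
        Design(
            {r: int(row[r]) for r in reactions}, label=str(row[LINE_NAME_COLUMN])
        )
        for _, row in df.iterrows()
    ]
    includes_wt = any(d.is_wt for d in designs)
    return DesignBatch(designs=designs, includes_wt=includes_wt)
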