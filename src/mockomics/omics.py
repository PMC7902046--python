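"""Synthetic omics tables derived from flux vectors.

Fluxes are turned into mock measurements by three deliberately simple rules:

* proteomics:       ``P_j = |V_j|/k + β``,   ``k = 0.1``
* transcriptomics:  ``T_j = P_j/q + γ``,     ``q = 0.833``
* metabolomics:     ``M_i = Σ_j |S_ij·V_j| / n_i`` over the ``n_i`` reactions
  that produce or consume metabolite ``i`` (no noise term)

``β`` and ``γ`` are seeded Gaussian draws with standard deviation equal to a
fraction (default 5%) of the signal, and values are clamped at zero.  The
proteomics rule uses the magnitude of the flux so that reversible reactions
carrying negative flux still yield a physical (non-negative) abundance while
preserving "no flux → no protein"; set ``signed_fluxes=True`` for the literal
signed form.  These relationships are mock by construction — linear stand-ins
loosely inspired by saturation kinetics, not enzyme models — but they keep the
generated data self-consistent across omics layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .batch import BatchTimeSeries
from .model import FluxState, MetabolicModel

logger = logging.getLogger(__name__)

UNIT_PROTEOMICS = "proteins/cell"
UNIT_TRANSCRIPTOMICS = "FPKM"
UNIT_METABOLOMICS = "mM"
OMICS_UNITS = {UNIT_PROTEOMICS, UNIT_TRANSCRIPTOMICS, UNIT_METABOLOMICS}

COLUMNS = ["time", "reaction_id", "feature_id", "value", "unit"]


@dataclass
class OmicsConfig:
    """Constants of the flux→omics rules.

    ``k`` and ``q`` are the (arbitrary) linear constants of the proteomics
    and transcriptomics rules; ``noise_fraction`` is the relative standard
    deviation of the additive noise.
    """

    k: float = 0.1
    q: float = 0.833
    noise_fraction: float = 0.05
    rng_seed: int = 0
    signed_fluxes: bool = False

    def validate(self) -> None:
        if self.k <= 0 or self.q <= 0:
            raise ValueError("k and q must be positive")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class OmicsTable:
    """Rows of (time, feature id, value, unit), one omics layer."""

    df: pd.DataFrame
    kind: str  # "proteomics" | "transcriptomics" | "metabolomics"

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"omics table missing columns {missing}")
        if len(self.df) and (self.df["value"] < 0).any():
            raise ValueError("omics values must be non-negative")
        bad = set(self.df["unit"]) - OMICS_UNITS
        if bad:
            raise ValueError(f"units outside the closed vocabulary: {bad}")

    def __len__(self) -> int:
        return len(self.df)

    def value(self, feature_id: str, time: float | None = None) -> float:
        sel = self.df[self.df["feature_id"] == feature_id]
        if time is not None:
            sel = sel[sel["time"] == time]
        return float(sel["value"].iloc[0])


def _noisy(signal: float, config: OmicsConfig, rng: np.random.Generator) -> float:
    sd = config.noise_fraction * abs(signal)
    noise = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
    return max(0.0, signal + noise)


def proteomics_from_fluxes(
    flux: FluxState,
    model: MetabolicModel,
    config: OmicsConfig | None = None,
    time: float = 0.0,
    rng: np.random.Generator | None = None,
) -> OmicsTable:
    """Protein abundance per mapped reaction: ``P_j = |V_j|/k + β``.

    Reactions absent from the model's feature map (exchanges, the biomass
    drain) are skipped with a logged warning.  Draws are consumed in the
    model's reaction order so row order cannot change the noise.
    """
    config = config or OmicsConfig()
    config.validate()
    rng = rng if rng is not None else config.rng()
    rows = []
    skipped = []
    for rxn in model.reaction_ids:
        if rxn not in model.feature_map:
            skipped.append(rxn)
            continue
        v = flux.fluxes[rxn]
        signal = (v if config.signed_fluxes else abs(v)) / config.k
        protein_id = model.feature_map[rxn][0]
        rows.append((time, rxn, protein_id, _noisy(signal, config, rng), UNIT_PROTEOMICS))
    if skipped:
        logger.warning("proteomics: skipped unmapped reactions %s", skipped)
    return OmicsTable(pd.DataFrame(rows, columns=COLUMNS), "proteomics")


def transcriptomics_from_proteomics(
    prot: OmicsTable,
    model: MetabolicModel,
    config: OmicsConfig | None = None,
    rng: np.random.Generator | None = None,
) -> OmicsTable:
    """Transcript abundance per protein row: ``T_j = P_j/q + γ`` (FPKM)."""
    config = config or OmicsConfig()
    config.validate()
    rng = rng if rng is not None else config.rng()
    rows = []
    for row in prot.df.itertuples(index=False):
        signal = row.value / config.q
        transcript_id = model.feature_map[row.reaction_id][1]
        rows.append(
            (row.time, row.reaction_id, transcript_id,
             _noisy(signal, config, rng), UNIT_TRANSCRIPTOMICS)
        )
    return OmicsTable(pd.DataFrame(rows, columns=COLUMNS), "transcriptomics")


def metabolomics_from_fluxes(
    flux: FluxState,
    model: MetabolicModel,
    time: float = 0.0,
) -> OmicsTable:
    """Metabolite level as the mean absolute incident flux (no noise).

    ``M_i = Σ_j |S_ij V_j| / n_i`` over the reactions with ``S_ij ≠ 0``; a
    metabolite participating in no reaction is excluded with a logged
    warning.  Zero incident flux gives exactly zero metabolite.
    """
    v = flux.vector(model)
    rows = []
    excluded = []
    for i, met in enumerate(model.metabolite_ids):
        incident = np.nonzero(model.S[i, :])[0]
        if incident.size == 0:
            excluded.append(met)
            continue
        value = float(np.abs(model.S[i, incident] * v[incident]).sum() / incident.size)
        feature_id = model.metabolite_measurement_ids.get(met, met)
        rows.append((time, "", feature_id, value, UNIT_METABOLOMICS))
    if excluded:
        logger.warning("metabolomics: metabolites in no reaction %s", excluded)
    return OmicsTable(pd.DataFrame(rows, columns=COLUMNS), "metabolomics")


def multiomics_from_series(
    model: MetabolicModel,
    series: BatchTimeSeries,
    config: OmicsConfig | None = None,
) -> dict[str, OmicsTable]:
    """All three omics layers for every time point of a batch series.

    One shared seeded generator is consumed across time points (proteomics
    then transcriptomics, per point, in reaction order), so the full table
    set is reproducible from ``config.rng_seed`` alone.
    """
    config = config or OmicsConfig()
    config.validate()
    rng = config.rng()
    prot_frames, trans_frames, met_frames = [], [], []
    for k, t in enumerate(series.times):
        flux = series.fluxes[k]
        prot = proteomics_from_fluxes(flux, model, config, time=float(t), rng=rng)
        trans = transcriptomics_from_proteomics(prot, model, config, rng=rng)
        metab = metabolomics_from_fluxes(flux, model, time=float(t))
        prot_frames.append(prot.df)
        trans_frames.append(trans.df)
        met_frames.append(metab.df)
    return {
        "proteomics": OmicsTable(
            pd.concat(prot_frames, ignore_index=True), "proteomics"
        ),
        "transcriptomics": OmicsTable(
            pd.concat(trans_frames, ignore_index=True), "transcriptomics"
        ),
        "metabolomics": OmicsTable(
            pd.concat(met_frames, ignore_index=True), "metabolomics"
        ),
    }
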