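"""Dual-luciferase RNAi-screen normalization, robust Z-scores and hit calling.

The screen measures an antioxidant-response-element firefly-luciferase
reporter (Fluc) against a constitutive Act5C renilla-luciferase control
(Rluc) in each well.  The Fluc/Rluc ratio cancels well-to-well transfection
and viability variation; per scoping unit (plate by default) the ratios are
converted to robust Z-scores, ``z = (ratio - median) / (1.4826 * MAD)``, with
the location and scale estimated from non-control wells only.  A gene is
called a pathway *inducer* when knockdown consistently suppresses the
reporter (z at or below -threshold for at least ``min_consistent`` of its
dsRNAs, none on the opposite side when the veto is active) and a *suppressor*
symmetrically on the positive side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: 1/Phi^-1(3/4): scales the median absolute deviation to a normal sigma
MAD_SCALE = 1.4826

INDUCER = "inducer"
SUPPRESSOR = "suppressor"
NONE = "none"


class DegenerateScaleError(ValueError):
    """Raised when a scoping unit has zero median absolute deviation."""


@dataclass(frozen=True)
class ScreenConfig:
    """Hit-calling parameters.

    z_threshold
        Robust-Z magnitude a dsRNA must reach (default 1.65, the one-sided
        normal 5% point used by the screen).
    min_consistent
        How many of a gene's dsRNAs must pass on the same side.  The default
        2-of-3 reproduces the published hit table, which lists genes whose
        third dsRNA stayed inside the threshold; a strict all-dsRNA rule is
        available by setting this to the dsRNA count.
    opposite_sign_veto
        If true, any dsRNA crossing the threshold on the opposite side vetoes
        the call (guards against off-target reagents).
    z_scope
        ``"plate"`` estimates median/MAD per plate (robust to plate effects,
        standard HTS practice); ``"screen"`` pools all wells.
    """

    z_threshold: float = 1.65
    min_consistent: int = 2
    opposite_sign_veto: bool = True
    z_scope: str = "plate"

    def __post_init__(self):
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.min_consistent < 1:
            raise ValueError("min_consistent must be >= 1")
        if self.z_scope not in ("plate", "screen"):
            raise ValueError("z_scope must be 'plate' or 'screen'")


def normalize_wells(plate: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the Fluc/Rluc reporter ratio per well.

    Wells with non-positive renilla signal (dead or untransfected wells)
    cannot be normalized; they are dropped and reported in a well-failure
    table rather than failing the whole plate.

    Returns ``(normalized, failures)`` where ``normalized`` carries every
    input column plus ``ratio`` and ``failures`` holds the rejected rows with
    a ``failure_reason`` column.
    """
    bad = plate["rluc"] <= 0
    failures = plate.loc[bad].copy()
    failures["failure_reason"] = "non-positive renilla signal"
    if bad.any():
        log.warning("dropping %d well(s) with non-positive renilla signal", int(bad.sum()))
    norm = plate.loc[~bad].copy()
    norm["ratio"] = norm["fluc"] / norm["rluc"]
    return norm, failures


def _robust_z(values: np.ndarray, reference: np.ndarray, unit: str) -> np.ndarray:
    med = float(np.median(reference))
    mad = float(np.median(np.abs(reference - med)))
    if mad == 0:
        raise DegenerateScaleError(
            f"scoping unit {unit!r} has zero median absolute deviation (constant ratios)"
        )
    return (values - med) / (MAD_SCALE * mad)


def compute_zscores(norm: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Robust Z-scores of the reporter ratios.

    Median and MAD are estimated over *non-control* wells of each scoping
    unit so that hit-rich control rows cannot distort the null scale, but
    control wells are still scored (their Z-values validate the assay).
    """
    if "ratio" not in norm.columns:
        raise ValueError("input lacks a 'ratio' column; run normalize_wells first")
    out = norm.copy()
    if cfg.z_scope == "plate":
        groups = [(str(p), idx) for p, idx in out.groupby("plate_id").groups.items()]
    else:
        groups = [("screen", out.index)]
    z = pd.Series(np.nan, index=out.index, dtype=float)
    for unit, idx in groups:
        sub = out.loc[idx]
        ref = sub.loc[sub["control_role"] == "none", "ratio"].to_numpy(float)
        if ref.size < 3:
            raise ValueError(f"scoping unit {unit!r} has fewer than 3 non-control wells")
        z.loc[idx] = _robust_z(sub["ratio"].to_numpy(float), ref, unit)
    out["z"] = z
    cols = ["gene_id", "dsrna_id", "z"]
    extra = [c for c in ("plate_id", "well_id", "control_role") if c in out.columns]
    return out[extra + cols].reset_index(drop=True)


def classify_genes(zscores: pd.DataFrame, cfg: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Apply the multi-dsRNA consensus rule gene by gene.

    A gene is an inducer when at least ``min_consistent`` dsRNAs have
    ``z <= -z_threshold`` and, with the veto active, no dsRNA has
    ``z >= +z_threshold``; suppressors mirror the rule on the positive side.
    Everything else is ``none``.  The output keeps a per-gene audit: the
    ordered z-values, the number of dsRNAs passing on the called side and the
    mean z used for ranking.
    """
    if zscores.empty:
        raise ValueError("empty z-score table")
    if zscores["z"].isna().any():
        raise ValueError("non-finite z-scores")
    records = []
    for gene, sub in zscores.groupby("gene_id", sort=True):
        zs = sub["z"].to_numpy(float)
        if zs.size == 0:
            raise ValueError(f"gene {gene!r} has no dsRNA z-scores")
        n_neg = int((zs <= -cfg.z_threshold).sum())
        n_pos = int((zs >= cfg.z_threshold).sum())
        inducer_ok = n_neg >= cfg.min_consistent and not (cfg.opposite_sign_veto and n_pos > 0)
        suppressor_ok = n_pos >= cfg.min_consistent and not (cfg.opposite_sign_veto and n_neg > 0)
        if inducer_ok and suppressor_ok:
            # only reachable with the veto off and both sides consistent:
            # contradictory evidence, no call
            call, n_passing = NONE, 0
        elif inducer_ok:
            call, n_passing = INDUCER, n_neg
        elif suppressor_ok:
            call, n_passing = SUPPRESSOR, n_pos
        else:
            call, n_passing = NONE, max(n_neg, n_pos)
        records.append(
            {
                "gene_id": gene,
                "call": call,
                "n_passing": n_passing,
                "mean_z": float(zs.mean()),
                "z_values": list(zs),
            }
        )
    return pd.DataFrame.from_records(records)


def rank_hits(calls: pd.DataFrame) -> pd.DataFrame:
    """Order gene calls for reporting.

    Inducers first, most negative mean z first (the strongest reporter
    suppression leads); then suppressors, most positive first; then the
    remaining genes.  Ties break on gene id.
    """
    if calls.empty:
        raise ValueError("empty call table")
    parts = []
    ind = calls[calls["call"] == INDUCER].sort_values(["mean_z", "gene_id"])
    sup = calls[calls["call"] == SUPPRESSOR].sort_values(
        ["mean_z", "gene_id"], ascending=[False, True]
    )
    rest = calls[calls["call"] == NONE].sort_values("gene_id")
    parts = [ind, sup, rest]
    return pd.concat(parts).reset_index(drop=True)


def write_gene_calls(calls: pd.DataFrame, path) -> None:
    """Write ranked calls as TSV: ``gene_id call n_passing mean_z z1 z2 ...``."""
    out = calls.copy()
    width = max(len(z) for z in out["z_values"])
    for i in range(width):
        out[f"z{i + 1}"] = [z[i] if i < len(z) else np.nan for z in out["z_values"]]
    out.drop(columns="z_values").to_csv(path, sep="\t", index=False)
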