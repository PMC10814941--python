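"""Cross-modal observation assembly, 0–1 scaling and class weighting.

The three modalities (DRS spectra, OCT B-scans, ultrasound images) are not
spatially co-registered, so per-tumor rows from the three feature tables are
paired at random: for each tumor every modality's rows are independently
permuted (seeded) and zipped, so each source row enters at most one fused
observation.  The fused table carries 6 DRS + 65 OCT + 13 US = 84 feature
columns keyed by ``tumor_id, label, obs_idx``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .octtexture import oct_feature_names
from .spectra import DRS_FEATURES
from .ultrasound import US_FEATURES

__all__ = [
    "DIAGNOSIS_LABELS",
    "BINARY_LABELS",
    "to_binary_label",
    "feature_columns",
    "MissingModalityError",
    "pair_modalities",
    "ScalingParams",
    "fit_minmax",
    "apply_minmax",
    "invert_minmax",
    "compute_class_weights",
    "write_fused",
]

#: The closed six-class diagnosis enumeration (five clinical forms of basal
#: cell carcinoma plus benign neoplasms).
DIAGNOSIS_LABELS = (
    "infiltrative_ulcerative_bcc",
    "pigmented_bcc",
    "superficial_bcc",
    "morpheaform_bcc",
    "nodular_bcc",
    "benign",
)

BINARY_LABELS = ("bcc", "benign")


def to_binary_label(label: str) -> str:
    """Coarsen a six-class diagnosis to the {bcc, benign} view."""
    if label == "benign":
        return "benign"
    if label in DIAGNOSIS_LABELS:
        return "bcc"
    raise ValueError(f"unknown diagnosis label {label!r}")


def feature_columns() -> list[str]:
    """The 84 fused feature column names (6 DRS + 65 OCT + 13 US)."""
    return list(DRS_FEATURES) + oct_feature_names() + list(US_FEATURES)


class MissingModalityError(ValueError):
    """A tumor has no rows for one of the three modalities."""


def _tumor_groups(df: pd.DataFrame, name: str) -> dict:
    required = {"tumor_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{name} table must have a tumor_id column")
    return {tid: grp.reset_index(drop=True) for tid, grp in df.groupby("tumor_id")}


def pair_modalities(
    drs: pd.DataFrame,
    oct_: pd.DataFrame,
    us: pd.DataFrame,
    labels: Mapping[str, str] | pd.DataFrame,
    seed: int,
) -> pd.DataFrame:
    """Randomly pair per-tumor modality rows into fused observations.

    For each tumor the observation count is the minimum of the three modality
    row counts; each modality's rows are permuted with an independent draw
    from a seeded generator and the permutations are zipped, so no source row
    is used twice.  The result is reproducible given ``seed``.

    Parameters
    ----------
    drs, oct_, us : DataFrame
        Per-modality feature tables with a ``tumor_id`` column plus that
        modality's feature columns.
    labels : mapping or DataFrame
        ``tumor_id -> diagnosis`` (or a DataFrame with ``tumor_id, label``).
    seed : int
        Pairing seed; required so the pairing is a logged, reproducible
        configuration choice.
    """
    if isinstance(labels, pd.DataFrame):
        labels = dict(zip(labels["tumor_id"], labels["label"]))
    for lab in labels.values():
        if lab not in DIAGNOSIS_LABELS:
            raise ValueError(f"unknown diagnosis label {lab!r}")

    groups = {
        "drs": _tumor_groups(drs, "drs"),
        "oct": _tumor_groups(oct_, "oct"),
        "us": _tumor_groups(us, "us"),
    }
    rng = np.random.default_rng(seed)
    fused_rows = []
    for tumor_id in sorted(labels):
        per_modality = {}
        for mod, tables in groups.items():
            if tumor_id not in tables or len(tables[tumor_id]) == 0:
                raise MissingModalityError(
                    f"tumor {tumor_id!r} has no rows for modality {mod!r}"
                )
            per_modality[mod] = tables[tumor_id]
        n_obs = min(len(t) for t in per_modality.values())
        perms = {
            mod: rng.permutation(len(t))[:n_obs] for mod, t in per_modality.items()
        }
        for k in range(n_obs):
            row: dict = {
                "tumor_id": tumor_id,
                "label": labels[tumor_id],
                "obs_idx": k,
            }
            for mod, cols in (
                ("drs", DRS_FEATURES),
                ("oct", oct_feature_names()),
                ("us", US_FEATURES),
            ):
                src = per_modality[mod].iloc[int(perms[mod][k])]
                for c in cols:
                    row[c] = src[c]
                row[f"{mod}_source_row"] = int(perms[mod][k])
            fused_rows.append(row)
    cols = ["tumor_id", "label", "obs_idx"] + feature_columns() + [
        "drs_source_row",
        "oct_source_row",
        "us_source_row",
    ]
    return pd.DataFrame(fused_rows, columns=cols)


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature (min, max) learned from a training partition."""

    minimum: pd.Series
    maximum: pd.Series


def fit_minmax(train: pd.DataFrame, columns: Sequence[str] | None = None) -> ScalingParams:
    """Learn per-feature min/max from training rows only."""
    cols = list(columns) if columns is not None else feature_columns()
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to fit scaling")
    sub = train[cols]
    return ScalingParams(minimum=sub.min(axis=0), maximum=sub.max(axis=0))


def apply_minmax(rows: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Scale features to (x − min)/(max − min).

    Constant training features map to 0; held-out values outside the training
    range extrapolate beyond [0, 1] (no clipping).
    """
    out = rows.copy()
    span = params.maximum - params.minimum
    for c in params.minimum.index:
        if span[c] == 0:
            out[c] = 0.0
        else:
            out[c] = (rows[c] - params.minimum[c]) / span[c]
    return out


def invert_minmax(rows: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Inverse of :func:`apply_minmax` on non-constant features."""
    out = rows.copy()
    span = params.maximum - params.minimum
    for c in params.minimum.index:
        if span[c] != 0:
            out[c] = rows[c] * span[c] + params.minimum[c]
    return out


def compute_class_weights(labels: Sequence[str] | pd.Series) -> dict[str, float]:
    """Inverse-frequency class weights, normalized to mean weight 1.

    ``w(c) = N / (K · count(c))`` where N is the total observation count and
    K the number of represented classes; the observation-weighted mean is 1,
    keeping loss magnitudes comparable across folds.
    """
    counts = pd.Series(labels).value_counts()
    if counts.empty:
        raise ValueError("no labels given")
    n, k = counts.sum(), len(counts)
    return {str(c): float(n / (k * counts[c])) for c in counts.index}


def write_fused(
    table: pd.DataFrame, path: str | Path, *, seed: int, scaling_mode: str
) -> None:
    """Write the fused CSV plus a JSON sidecar recording seed and scaling."""
    path = Path(path)
    table.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"pairing_seed": seed, "scaling_mode": scaling_mode}, indent=2)
    )
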