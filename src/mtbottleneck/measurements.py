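"""Measurement tables and synthetic measurement generation.

The inference layer consumes tables of developmental mtDNA statistics: per
time point either a mean copy number or a normalised heteroplasmy variance
V'(h) = V(h)/(E(h)(1-E(h))), together with the number of cells the statistic
was computed from.  Mature oocytes of the next generation are placed at
100 dpc by convention.

The synthetic generator simulates independent germline lineages from a known
ground-truth parameterisation and subsamples them with the same small sample
sizes real oocyte studies have, emitting both the summary statistics and the
raw per-cell heteroplasmies.  It provides ground-truth-known inputs for every
inference test; a shipped CSV template documents the schema for transcribing
published measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import MechanismConfig, PhaseSchedule
from .simulate import simulate_ensemble

__all__ = [
    "MeasurementSet",
    "SyntheticSpec",
    "MeasurementError",
    "load_measurements",
    "generate_measurements",
    "train_test_split_alternating",
    "coverage_check",
    "CoverageReport",
    "MATURE_OOCYTE_DPC",
    "COPY_MEAN",
    "NORM_HET_VAR",
]

MATURE_OOCYTE_DPC = 100.0
COPY_MEAN = "copy_number_mean"
NORM_HET_VAR = "normalised_het_variance"
_STATISTICS = (COPY_MEAN, NORM_HET_VAR)
_COLUMNS = ["source", "t_dpc", "statistic", "value", "n"]


class MeasurementError(ValueError):
    """Raised for malformed measurement tables."""


@dataclass
class MeasurementSet:
    """A validated table of observed or simulated summary statistics."""

    df: pd.DataFrame

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        missing = set(_COLUMNS) - set(self.df.columns)
        if missing:
            raise MeasurementError(f"missing columns: {sorted(missing)}")
        self.df = self.df[_COLUMNS].copy()
        for i, row in self.df.iterrows():
            line = i + 2  # header is line 1
            if row["statistic"] not in _STATISTICS:
                raise MeasurementError(f"line {line}: unknown statistic {row['statistic']!r}")
            if not np.isfinite(row["value"]):
                raise MeasurementError(f"line {line}: non-numeric value")
            if row["statistic"] == NORM_HET_VAR and row["value"] < 0:
                raise MeasurementError(f"line {line}: negative variance {row['value']}")
            if row["statistic"] == COPY_MEAN and row["value"] <= 0:
                raise MeasurementError(f"line {line}: copy-number mean must be positive")
            if not (row["n"] >= 1 and float(row["n"]).is_integer()):
                raise MeasurementError(f"line {line}: n must be a positive integer")
            if not np.isfinite(row["t_dpc"]) or row["t_dpc"] < 0:
                raise MeasurementError(f"line {line}: bad time {row['t_dpc']}")
        self.df["n"] = self.df["n"].astype(int)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["t_dpc"].to_numpy()

    def subset(self, statistic: str) -> pd.DataFrame:
        return self.df[self.df["statistic"] == statistic]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "MeasurementSet":
        return cls(pd.DataFrame(records, columns=_COLUMNS))

    @classmethod
    def empty(cls) -> "MeasurementSet":
        return cls(pd.DataFrame(columns=_COLUMNS))


def load_measurements(path) -> MeasurementSet:
    """Read a measurement CSV (template placeholder rows are dropped).

    Lines beginning with ``#`` are comments.  Rows with an empty ``value``
    are transcription placeholders and are skipped; rows labelled as mature
    oocytes with no time are assigned the 100 dpc convention.  Malformed
    rows raise :class:`MeasurementError` with their line number.
    """
    try:
        df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MeasurementError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        return MeasurementSet.empty()
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise MeasurementError(f"missing columns: {sorted(missing)}")
    mature = df["source"].astype(str).str.contains("mature", case=False)
    df.loc[mature & df["t_dpc"].isna(), "t_dpc"] = MATURE_OOCYTE_DPC
    df = df[df["value"].notna()].reset_index(drop=True)
    if df.empty:
        return MeasurementSet.empty()
    return MeasurementSet(df)


def template_path() -> Path:
    """Path of the shipped transcription template CSV."""
    return Path(str(resources.files("mtbottleneck") / "templates" / "literature_template.csv"))


# ---------------------------------------------------------------------------
# Synthetic measurement generation


def default_design() -> list[tuple[float, str, int]]:
    """Observation design emulating the published developmental datasets.

    Copy-number means through development with small n, and normalised
    heteroplasmy variances from modest numbers of sampled oocytes, ending
    with the mature-oocyte point at 100 dpc.
    """
    design: list[tuple[float, str, int]] = []
    for t in (0.0, 7.5, 8.5, 10.5, 13.5, 21.0, 30.0, 45.0, 60.0, 100.0):
        design.append((t, COPY_MEAN, 5))
    # oocyte sampling ages span late development (24-61 dpc) plus the
    # earlier germ-cell measurements and the mature-oocyte convention point;
    # each set has tens of cells, as in the published studies
    for t in (7.5, 10.5, 13.5, 16.0, 18.5, 21.0, 24.0, 27.0, 30.0, 35.0,
              40.0, 50.0, 61.0, 100.0):
        design.append((t, NORM_HET_VAR, 40))
    return design


@dataclass
class SyntheticSpec:
    """Ground truth plus observation design for synthetic measurements."""

    cfg: MechanismConfig
    sched: PhaseSchedule
    design: list[tuple[float, str, int]] = field(default_factory=default_design)
    seed: int | np.random.Generator = 0

    def __post_init__(self):
        for t, stat, n in self.design:
            if stat == NORM_HET_VAR and n < 2:
                raise MeasurementError("variance statistics need n_samples >= 2")


def generate_measurements(
    spec: SyntheticSpec,
) -> tuple[MeasurementSet, pd.DataFrame, dict]:
    """Simulate a synthetic measurement set from a known parameterisation.

    Independent cells are simulated for every design row; extinct cells are
    replaced (with a warning and a count in the returned info dict) so each
    heteroplasmy statistic uses the requested number of surviving cells.
    Returns the summary :class:`MeasurementSet`, the raw per-cell
    heteroplasmies (``group_id, t_dpc, h``), and a ground-truth sidecar dict.
    """
    rng = np.random.default_rng(spec.seed) if not isinstance(spec.seed, np.random.Generator) \
        else spec.seed
    records = []
    cells = []
    n_resampled = 0
    for gid, (t, stat, n) in enumerate(spec.design):
        need = n
        draws = []
        attempts = 0
        while need > 0:
            batch = max(need + 4, int(1.2 * need))
            ens = simulate_ensemble(spec.cfg, spec.sched, [t], batch, rng)
            m = ens.m[0][ens.valid]
            h = ens.h[0][ens.valid]
            # sampled oocytes are surviving cells: extinct lineages are
            # replaced for both statistic types
            if stat == COPY_MEAN:
                alive = m[m > 0]
            else:
                alive = h[~np.isnan(h)]
            n_resampled += (batch - alive.size)
            take = alive[: need]
            draws.extend(take.tolist())
            need -= take.size
            attempts += 1
            if attempts > 50:
                raise MeasurementError(
                    f"could not draw {n} surviving cells at t={t}; "
                    "parameterisation too extinction-prone"
                )
        draws = np.asarray(draws[:n])
        if stat == COPY_MEAN:
            value = float(draws.mean())
        else:
            hbar = float(draws.mean())
            if 0.0 < hbar < 1.0:
                value = float(draws.var(ddof=1) / (hbar * (1.0 - hbar)))
            else:
                value = 0.0
            for hv in draws:
                cells.append({"group_id": gid, "t_dpc": t, "h": float(hv)})
        records.append({
            "source": "synthetic", "t_dpc": t, "statistic": stat,
            "value": value, "n": n,
        })
    if n_resampled:
        warnings.warn(f"{n_resampled} extinct cells were resampled", stacklevel=2)
    info = {
        "mechanism": spec.cfg.to_dict(),
        "schedule": spec.sched.to_dict(),
        "sigma": spec.sched.total_turnover(),
        "n_resampled_extinct": n_resampled,
    }
    return (MeasurementSet.from_records(records),
            pd.DataFrame(cells, columns=["group_id", "t_dpc", "h"]),
            info)


# ---------------------------------------------------------------------------
# Train/test split and predictive coverage


def train_test_split_alternating(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split sampled oocyte groups into train/test by alternation in time.

    Groups (``group_id``) are ordered by their sampling time; odd-indexed
    groups (1-based: 1st, 3rd, ...) form the training set, even-indexed the
    test set.  Deterministic; input order is irrelevant.
    """
    if "group_id" not in samples.columns or "t_dpc" not in samples.columns:
        raise MeasurementError("need columns group_id and t_dpc")
    order = (samples.groupby("group_id")["t_dpc"].mean().sort_values(kind="stable"))
    train_ids = [g for i, g in enumerate(order.index) if i % 2 == 0]
    test_ids = [g for i, g in enumerate(order.index) if i % 2 == 1]
    train = samples[samples["group_id"].isin(train_ids)].reset_index(drop=True)
    test = samples[samples["group_id"].isin(test_ids)].reset_index(drop=True)
    return train, test


@dataclass
class CoverageReport:
    """Outcome of checking per-cell test samples against model predictions."""

    outside_fraction: float
    n_outside: int
    n_total: int
    group_pvalues: dict
    level: float = 0.95


def coverage_check(
    test_samples: pd.DataFrame,
    models: Sequence[tuple[MechanismConfig, PhaseSchedule]] | tuple,
    rng: np.random.Generator | int = 0,
    n_pred: int = 2000,
    level: float = 0.95,
) -> CoverageReport:
    """Compare withheld per-cell heteroplasmies against predictive bands.

    For each test group, a posterior-predictive sample of cells is simulated
    at the group's time from the supplied parameterisation(s); the central
    ``level`` band of the mean-standardised heteroplasmy transform is
    computed, and the fraction of test cells falling outside it is returned,
    along with a two-sample Anderson-Darling p-value per group (distribution
    identity test on the raw heteroplasmies).
    """
    from scipy.stats import anderson_ksamp

    from .moments import het_transform

    if test_samples.empty:
        raise MeasurementError("empty test set")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(models, tuple) and len(models) == 2 and not isinstance(models[0], tuple):
        models = [models]
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2

    n_outside = 0
    n_total = 0
    pvals: dict = {}
    per_model = max(n_pred // len(models), 2)
    for gid, grp in test_samples.groupby("group_id"):
        t = float(grp["t_dpc"].iloc[0])
        preds = []
        for cfg, sched in models:
            ens = simulate_ensemble(cfg, sched, [t], per_model, rng)
            h = ens.h[0][ens.valid]
            preds.append(h[~np.isnan(h)])
        pred = np.concatenate(preds)
        e_pred = float(pred.mean())
        e_pred = min(max(e_pred, 1e-9), 1 - 1e-9)
        tp = het_transform(np.clip(pred, 1e-12, 1 - 1e-12), e_pred)
        band = np.percentile(tp, [lo_q, hi_q])
        th = het_transform(np.clip(grp["h"].to_numpy(), 1e-12, 1 - 1e-12), e_pred)
        n_outside += int(((th < band[0]) | (th > band[1])).sum())
        n_total += th.size
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = anderson_ksamp([grp["h"].to_numpy(), pred])
                pvals[gid] = float(res.pvalue)
            except ValueError:
                pvals[gid] = np.nan
    return CoverageReport(
        outside_fraction=n_outside / n_total, n_outside=n_outside,
        n_total=n_total, group_pvalues=pvals, level=level,
    )
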