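"""Cohort preprocessing: imputation, row removal, target construction,
label encoding, splitting and leakage-free min-max scaling.

The stages mirror how a pre-operative registry extract is prepared for
modelling: reference-based conditional-mean imputation (BMI from weight and
height; blood pressures from the hypertension stratum), removal of the few
rows whose missingness cannot be repaired (refusing if that would exceed the
conventional 5% benchmark), construction of the total length-of-stay target
as the sum of its two day-count components, deterministic label encoding and
min-max scaling fitted on training rows only.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EncodedMatrix",
    "ScalerParams",
    "SplitIndices",
    "impute_bmi",
    "impute_bp",
    "drop_sparse_rows",
    "build_target",
    "encode",
    "decode",
    "split",
    "scale_fit",
    "scale_apply",
    "preprocess_table",
]

_DROP_FLAG = "_drop_flag"
_ROW_DROP_COLUMNS = ("pulmonary_artery_done", "last_wbc_count", "pulmonary_insufficiency")
_TARGET_COMPONENTS = ("admission_to_surgery", "LOS_Surgery_to_discharge")
_REMOVE_AFTER_TARGET = ("TempSNO", "date_of_admission", "date_of_surgery",
                        "date_of_discharge", "weight", "height")


@dataclasses.dataclass
class EncodedMatrix:
    """Numeric design matrix with per-column metadata and the LoS target."""

    values: np.ndarray                    # (n, p) float
    columns: list                         # [(name, kind, encoding-map-or-None), ...]
    target: np.ndarray                    # (n,) float, days

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.columns]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)


@dataclasses.dataclass
class ScalerParams:
    """Per-column (min, max) learned from training rows only."""

    bounds: dict  # name -> (min, max)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {k: [float(a), float(b)] for k, (a, b) in self.bounds.items()}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        raw = json.loads(Path(path).read_text())
        return cls(bounds={k: (v[0], v[1]) for k, v in raw.items()})


@dataclasses.dataclass
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    seed: int


def impute_bmi(table: pd.DataFrame) -> pd.DataFrame:
    """Fill missing BMI as weight [kg] / (height [m])^2; flag unrepairable rows."""
    out = table.copy()
    if _DROP_FLAG not in out.columns:
        out[_DROP_FLAG] = False
    missing = out["BMI"].isna()
    can_fix = missing & out["weight"].notna() & out["height"].notna()
    out.loc[can_fix, "BMI"] = (out.loc[can_fix, "weight"]
                               / (out.loc[can_fix, "height"] / 100.0) ** 2)
    out.loc[missing & ~can_fix, _DROP_FLAG] = True
    return out


def impute_bp(table: pd.DataFrame, hyper_mean: float | None = 124.0,
              normo_mean: float | None = 117.0,
              columns: tuple = ("BPsystolic", "diastolic"),
              stat_rows: np.ndarray | None = None) -> pd.DataFrame:
    """Conditional-mean imputation of blood pressures by hypertension stratum.

    With ``hyper_mean``/``normo_mean`` given (defaults are the published
    reference means for systolic pressure, 124/117 mmHg), missing systolic
    values are filled with them directly.  Passing ``None`` computes the
    stratum means of each column from its non-missing rows — the behaviour the
    pipeline uses, so imputation adapts to the cohort at hand; ``stat_rows``
    restricts that computation to training rows so no test statistic leaks in.
    Diastolic pressure always uses computed stratum means (no published
    constants exist for it).
    """
    out = table.copy()
    if _DROP_FLAG not in out.columns:
        out[_DROP_FLAG] = False
    if "hypertension" not in out.columns:
        raise KeyError("hypertension column required for blood-pressure imputation")
    hyper = out["hypertension"]
    stats_pool = out if stat_rows is None else out.iloc[stat_rows]
    for col in columns:
        if col not in out.columns:
            continue
        missing = out[col].isna()
        if not missing.any():
            continue
        out.loc[missing & hyper.isna(), _DROP_FLAG] = True
        for label in ("Yes", "No"):
            if col == "BPsystolic" and label == "Yes" and hyper_mean is not None:
                fill = hyper_mean
            elif col == "BPsystolic" and label == "No" and normo_mean is not None:
                fill = normo_mean
            else:
                obs = stats_pool.loc[(stats_pool["hypertension"] == label)
                                     & stats_pool[col].notna(), col]
                fill = float(obs.mean())
            out.loc[missing & (hyper == label), col] = fill
    return out


def drop_sparse_rows(table: pd.DataFrame, benchmark: float = 0.05) -> pd.DataFrame:
    """Remove rows still missing a non-imputable column (or flagged upstream).

    Refuses when the removal would exceed the 5% benchmark below which
    complete-case deletion is considered safe.
    """
    out = table.copy()
    drop = out[_DROP_FLAG].to_numpy(dtype=bool) if _DROP_FLAG in out.columns \
        else np.zeros(len(out), dtype=bool)
    for col in _ROW_DROP_COLUMNS:
        if col in out.columns:
            drop |= out[col].isna().to_numpy()
    # blood pressures can only be imputed when the hypertension stratum is known
    if "hypertension" in out.columns:
        hyper_na = out["hypertension"].isna().to_numpy()
        for col in ("BPsystolic", "diastolic"):
            if col in out.columns:
                drop |= out[col].isna().to_numpy() & hyper_na
    frac = drop.mean() if len(out) else 0.0
    if frac > benchmark:
        raise ValueError(
            f"row removal would drop {frac:.1%} of rows, above the "
            f"{benchmark:.0%} benchmark")
    out = out.loc[~drop].reset_index(drop=True)
    return out.drop(columns=[_DROP_FLAG], errors="ignore")


def build_target(table: pd.DataFrame) -> pd.DataFrame:
    """Append LOS = admission_to_surgery + LOS_Surgery_to_discharge and drop
    the identifier, date, weight/height and component columns."""
    for col in _TARGET_COMPONENTS:
        if (table[col] < 0).any():
            raise ValueError(f"negative values in component column {col!r}")
    out = table.copy()
    out["LOS"] = out[_TARGET_COMPONENTS[0]] + out[_TARGET_COMPONENTS[1]]
    remove = [c for c in (*_REMOVE_AFTER_TARGET, *_TARGET_COMPONENTS) if c in out.columns]
    return out.drop(columns=remove)


def encode(table: pd.DataFrame, target: str = "LOS",
           label_sets: dict | None = None) -> EncodedMatrix:
    """Label-encode categorical columns (alphabetically sorted labels, codes
    from 0); continuous columns pass through unchanged.

    ``label_sets`` optionally supplies each column's full label universe
    (e.g. from a cohort column dictionary); labels observed nowhere in the
    given rows then still receive a stable code, keeping the maps entirely
    data-independent.  Without it, maps come from the observed labels.
    """
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values remain in columns {bad}")
    names, kinds, maps, cols = [], [], [], []
    y = table[target].to_numpy(dtype=float)
    for name in table.columns:
        if name == target:
            continue
        col = table[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            if label_sets is not None and name in label_sets:
                labels = sorted(map(str, label_sets[name]))
                observed = set(map(str, pd.unique(col)))
                if not observed <= set(labels):
                    raise ValueError(
                        f"label(s) {sorted(observed - set(labels))} in column "
                        f"{name!r} missing from the declared label set")
            else:
                labels = sorted(map(str, pd.unique(col)))
            mapping = {lab: i for i, lab in enumerate(labels)}
            cols.append(col.astype(str).map(mapping).to_numpy(dtype=float))
            names.append(name); kinds.append("categorical"); maps.append(mapping)
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name); kinds.append("continuous"); maps.append(None)
    values = np.column_stack(cols) if cols else np.empty((len(table), 0))
    return EncodedMatrix(values=values,
                         columns=list(zip(names, kinds, maps)),
                         target=y)


def decode(matrix: EncodedMatrix) -> pd.DataFrame:
    """Invert :func:`encode` (round-trip identity on the encoded cells)."""
    out = {}
    for j, (name, kind, mapping) in enumerate(matrix.columns):
        col = matrix.values[:, j]
        if kind == "categorical":
            inverse = {v: k for k, v in mapping.items()}
            out[name] = np.array([inverse[int(v)] for v in col], dtype=object)
        else:
            out[name] = col
    frame = pd.DataFrame(out)
    frame["LOS"] = matrix.target
    return frame


def apply_encoding(table: pd.DataFrame, matrix: EncodedMatrix,
                   target: str = "LOS") -> EncodedMatrix:
    """Encode ``table`` with the maps learned in ``matrix``; unseen labels error."""
    cols = []
    for name, kind, mapping in matrix.columns:
        col = table[name]
        if kind == "categorical":
            vals = col.astype(str)
            unseen = set(pd.unique(vals)) - set(mapping)
            if unseen:
                raise ValueError(f"unseen label(s) {sorted(unseen)} in column {name!r}")
            cols.append(vals.map(mapping).to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    return EncodedMatrix(values=np.column_stack(cols), columns=matrix.columns,
                         target=table[target].to_numpy(dtype=float))


def split(n: int, fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Seeded uniform 80/20 row partition; |train| = round(fraction * n)."""
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return SplitIndices(train=np.sort(perm[:n_train]),
                        test=np.sort(perm[n_train:]), seed=seed)


def scale_fit(matrix: EncodedMatrix, train: np.ndarray,
              scale_categorical: bool = True) -> ScalerParams:
    """Learn per-column (min, max) from training rows only."""
    bounds = {}
    for j, (name, kind, _) in enumerate(matrix.columns):
        if kind == "categorical" and not scale_categorical:
            continue
        col = matrix.values[train, j]
        bounds[name] = (float(col.min()), float(col.max()))
    return ScalerParams(bounds=bounds)


def scale_apply(matrix: EncodedMatrix, params: ScalerParams) -> EncodedMatrix:
    """Apply x' = (x - min) / (max - min); constant training columns map to 0.

    Test values outside the training range are allowed to fall outside [0, 1].
    """
    values = matrix.values.copy()
    for j, (name, _, _) in enumerate(matrix.columns):
        if name not in params.bounds:
            continue
        lo, hi = params.bounds[name]
        if hi > lo:
            values[:, j] = (values[:, j] - lo) / (hi - lo)
        else:
            values[:, j] = 0.0
    return EncodedMatrix(values=values, columns=matrix.columns, target=matrix.target)


def save_matrix(matrix: EncodedMatrix, out_dir: str | Path, name: str) -> None:
    """Write an encoded matrix as ``<name>.csv`` plus ``<name>.meta.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame = matrix.frame()
    frame["LOS"] = matrix.target
    frame.to_csv(out / f"{name}.csv", index=False)
    meta = [{"name": n, "kind": k, "encoding": m} for n, k, m in matrix.columns]
    (out / f"{name}.meta.json").write_text(json.dumps(meta, indent=1))


def load_matrix(out_dir: str | Path, name: str) -> EncodedMatrix:
    out = Path(out_dir)
    frame = pd.read_csv(out / f"{name}.csv")
    meta = json.loads((out / f"{name}.meta.json").read_text())
    columns = [(m["name"], m["kind"], m["encoding"]) for m in meta]
    values = frame[[m["name"] for m in meta]].to_numpy(dtype=float)
    return EncodedMatrix(values=values, columns=columns,
                         target=frame["LOS"].to_numpy(dtype=float))


def preprocess_table(table: pd.DataFrame, seed: int = 0, fraction: float = 0.8,
                     scale_categorical: bool = True,
                     bp_means: tuple | None = None,
                     label_sets: dict | None = None,
                     ) -> tuple[EncodedMatrix, EncodedMatrix, SplitIndices, ScalerParams]:
    """Run the full preparation chain and return scaled train/test matrices.

    ``bp_means`` of ``(hyper, normo)`` overrides the computed-from-data
    blood-pressure imputation with fixed reference means.

    Every data-driven fit — blood-pressure stratum means, encoding maps and
    scaler bounds — is learned on training rows only; the split itself depends
    only on the row count and seed, so it can precede imputation.
    """
    t = impute_bmi(table)
    t = drop_sparse_rows(t)
    t = build_target(t)
    idx = split(len(t), fraction=fraction, seed=seed)
    if "hypertension" in t.columns:
        if bp_means is None:
            t = impute_bp(t, hyper_mean=None, normo_mean=None, stat_rows=idx.train)
        else:
            t = impute_bp(t, hyper_mean=bp_means[0], normo_mean=bp_means[1],
                          stat_rows=idx.train)
        t = t.drop(columns=[_DROP_FLAG], errors="ignore")
    train_mat = encode(t.iloc[idx.train], label_sets=label_sets)
    test_mat = apply_encoding(t.iloc[idx.test], train_mat)
    params = scale_fit(train_mat, np.arange(len(idx.train)),
                       scale_categorical=scale_categorical)
    train = scale_apply(train_mat, params)
    test = scale_apply(test_mat, params)
    return train, test, idx, params
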