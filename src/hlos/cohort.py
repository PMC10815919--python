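"""Synthetic cardiac-surgery cohort generation.

Two modes are provided:

``realistic``
    Emulates the marginal structure of a pre-operative CABG registry: one row
    per patient with an identifier, admission/surgery/discharge dates, twelve
    continuous clinical variables and 52 categorical variables (68 columns in
    total).  The two length-of-stay components (days from admission to surgery
    and days from surgery to discharge) are right-skewed negative-binomial
    counts coupled through a Gaussian copula so that the total LoS reproduces
    the published cohort moments (mean 8.3 days, sd 3.7, min 1, max 65).

``model_faithful``
    Draws LoS exactly from the hierarchical truncated-normal generative model
    with known per-level intercepts and coefficients, for parameter-recovery
    experiments.  The ground-truth parameters are returned alongside the table.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "default_spec",
    "default_truth",
    "generate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "LEVEL_EDGES",
]

#: Half-open LoS bin edges used as hierarchy levels: [0,10), [10,20), [20,30), [30,inf).
LEVEL_EDGES = (10.0, 20.0, 30.0)

# Gaussian-copula correlation between the two LoS components, calibrated once so
# that sd(total LoS) matches the published 3.7 days (independent components
# give ~3.55 because the printed component sds are 1.94 and 2.97).
_LOS_COPULA_RHO = 0.105

_ID_COLUMN = "TempSNO"
_DATE_COLUMNS = ("date_of_admission", "date_of_surgery", "date_of_discharge")


@dataclasses.dataclass
class GroundTruth:
    """Known generative parameters of a model-faithful cohort.

    ``beta0`` holds one intercept per LoS level (days), ``beta`` the per-level
    coefficient matrix (days per unit of the [0,1]-scaled feature), ``sigma``
    the shared truncated-normal noise scale and ``level_of_record`` the level
    index each record was drawn from.
    """

    beta0: np.ndarray          # (levels,)
    beta: np.ndarray           # (levels, features)
    sigma: float
    level_of_record: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta0 = np.asarray(self.beta0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.level_of_record is not None:
            self.level_of_record = np.asarray(self.level_of_record, dtype=int)

    @property
    def n_levels(self) -> int:
        return len(self.beta0)


@dataclasses.dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``continuous_specs`` maps a column name to ``(family, loc, scale, lo, hi)``
    where family is ``"truncnorm"`` (clinical measurements) or ``"nbinom"``
    (day counts; ``lo`` acts as an additive shift so the support starts there).
    ``categorical_specs`` maps a column name to ``(labels, probabilities)``.
    """

    n_patients: int
    mode: str = "realistic"
    seed: int = 0
    continuous_specs: dict = dataclasses.field(default_factory=dict)
    categorical_specs: dict = dataclasses.field(default_factory=dict)
    missingness: dict = dataclasses.field(default_factory=dict)
    level_proportions: tuple = (0.80, 0.15, 0.04, 0.01)
    n_features: int = 8
    truth: GroundTruth | None = None
    los_copula_rho: float = _LOS_COPULA_RHO
    los_cap: float = 65.0
    # Conditional blood-pressure structure: systolic / diastolic means and
    # within-group sds stratified by the hypertension label.
    bp_conditional: dict = dataclasses.field(default_factory=lambda: {
        "BPsystolic": {"Yes": 124.0, "No": 117.0, "sd": 15.56},
        "diastolic": {"Yes": 73.0, "No": 67.2, "sd": 9.19},
    })

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("invalid spec: n_patients must be >= 1")
        if self.mode not in ("realistic", "model_faithful"):
            raise ValueError(f"invalid spec: unknown mode {self.mode!r}")
        for name, (labels, probs) in self.categorical_specs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"invalid spec: probabilities of {name!r} do not sum to 1")
            if len(labels) != len(probs):
                raise ValueError(f"invalid spec: labels/probabilities mismatch in {name!r}")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 0.05:
                raise ValueError(f"invalid spec: missingness rate for {name!r} outside [0, 0.05]")
        if self.mode == "model_faithful":
            if abs(sum(self.level_proportions) - 1.0) > 1e-9:
                raise ValueError("invalid spec: level proportions must sum to 1")


def _norm(counts) -> tuple:
    counts = np.asarray(counts, dtype=float)
    return tuple(counts / counts.sum())


def default_spec(n_patients: int = 5363, seed: int = 0) -> CohortSpec:
    """Packaged realistic-mode calibration of the synthetic cohort.

    Continuous marginals follow the published cohort summary (e.g. age mean
    58.07 sd 8.66 on [23, 90]); categorical frequencies follow the published
    counts (e.g. 954 of 5314 patients female); per-column missingness rates
    follow the published audit (BPsystolic 0.48%, five further columns 0.41%).
    Categorical prevalences that the source tables do not report are fixed at
    plausible pre-operative registry values and documented in the methods note.
    """
    continuous = {
        # family, loc (mean), scale (sd), lo, hi
        "admission_to_surgery": ("nbinom", 2.26, 1.94, 0, 21),
        "LOS_Surgery_to_discharge": ("nbinom", 6.04, 2.97, 1, 59),
        "last_wbc_count": ("truncnorm", 9.48, 2.77, 2.8, 48.8),
        "patient_age": ("truncnorm", 58.07, 8.66, 23, 90),
        "last_hematocrit": ("truncnorm", 40.51, 4.92, 21.2, 56.2),
        "last_cretenine_preop": ("truncnorm", 1.14, 0.63, 0.41, 13.3),
        "BPsystolic": ("truncnorm", 122.49, 15.94, 76, 199),
        "diastolic": ("truncnorm", 70.36, 9.63, 27, 117),
        "ejection_fraction": ("truncnorm", 42.89, 11.18, 10, 65),
        "weight": ("truncnorm", 71.87, 12.74, 36, 128),
        "height": ("truncnorm", 163.6, 8.33, 123, 191),
        # BMI is derived as weight / (height in m)^2, keeping it consistent
        # with the imputation rule; listed here for completeness of metadata.
        "BMI": ("derived", 26.82, 4.35, 14.82, 47.08),
    }
    yes_no = ("Yes", "No")
    categorical = {
        # published frequencies
        "gender_id": (("Male", "Female"), _norm([4360, 954])),
        "pulmonary_artery_done": (yes_no, _norm([2205, 3109])),
        "Active_tobacco_use": (yes_no, _norm([1308, 3975])),
        "f_history_cad": (yes_no, _norm([2664, 2699])),
        "diabetes": (("No", "Yes (Non-Insulin Dependent)", "Yes (Insulin Dependent)"),
                     _norm([2067, 2211, 1085])),
        "myocardial_infarction": (yes_no, _norm([3816, 1547])),
        "MI_timing": (("No MI", "<6 h", ">6-24 h", "1-7 days", "8-21 days", ">21 days"),
                      _norm([1584, 16, 26, 1473, 938, 1326])),
        "congestive_heart_failure": (yes_no, _norm([471, 4892])),
        "NYHA_class": (("Not applicable", "NYHA I", "NYHA II", "NYHA III", "NYHA IV"),
                       _norm([2482, 62, 1059, 1513, 247])),
        "Cardiac_Presentation_on_Admission": (
            ("No Symptoms of Angina", "Symptoms but unlikely to be ischemic",
             "Stable Angina", "Unstable Angina", "Non-ST Elevation MI", "ST Elevation MI"),
            _norm([301, 370, 575, 1664, 1778, 675])),
        # prevalences chosen once at plausible registry values (not published)
        "hypertension": (yes_no, (0.55, 0.45)),
        "arrhythmia": (yes_no, (0.06, 0.94)),
        "Arrhythmia_Type_Sust_VT_VF": (yes_no, (0.02, 0.98)),
        "lipid_lowering": (yes_no, (0.70, 0.30)),
        "Prior_PCI": (yes_no, (0.15, 0.85)),
        "resuscitation": (yes_no, (0.01, 0.99)),
        "Cerebovascular_disease": (yes_no, (0.05, 0.95)),
        "dialysis": (yes_no, (0.02, 0.98)),
        "pulmonary_insufficiency": (("None", "Mild", "Moderate", "Severe"),
                                    (0.90, 0.07, 0.025, 0.005)),
        "steroids": (yes_no, (0.02, 0.98)),
        "previous_coronary_bypass": (yes_no, (0.02, 0.98)),
        "Statin": (yes_no, (0.75, 0.25)),
        "inotropes": (yes_no, (0.03, 0.97)),
        "previous_valve": (yes_no, (0.01, 0.99)),
        "Mitral_regurgitation": (("None", "Mild", "Moderate", "Severe"),
                                 (0.55, 0.30, 0.12, 0.03)),
        "Angina_class": (("No Angina", "CCS I", "CCS II", "CCS III", "CCS IV"),
                         (0.20, 0.10, 0.30, 0.30, 0.10)),
        "FirstCVSurgery": (yes_no, (0.97, 0.03)),
        "PCI_timing": (("No PCI", "<6 h", "6-24 h", "1-7 days", ">7 days"),
                       (0.85, 0.01, 0.01, 0.05, 0.08)),
        "warfarin": (yes_no, (0.02, 0.98)),
        "ace_inhibitors": (yes_no, (0.45, 0.55)),
        "CABG_status": (("Elective", "Urgent", "Emergent", "Emergent Salvage"),
                        (0.70, 0.25, 0.045, 0.005)),
        "adp_inhibitors_within_5days": (yes_no, (0.35, 0.65)),
        "Carotid_disease": (yes_no, (0.05, 0.95)),
        "nitratesIV": (yes_no, (0.20, 0.80)),
        "cardiogenic_shock": (yes_no, (0.02, 0.98)),
        "aspirin": (yes_no, (0.90, 0.10)),
        "family_history_of_cardiac_disease": (yes_no, (0.30, 0.70)),
        "intracardiac_device": (yes_no, (0.01, 0.99)),
        "left_main_disease": (yes_no, (0.12, 0.88)),
        "beta_blockers": (yes_no, (0.80, 0.20)),
        "pulmonary_artery_hypertension": (yes_no, (0.10, 0.90)),
        "bronchodilators": (yes_no, (0.05, 0.95)),
        "Coronaries_diseased": (("One", "Two", "Three"), (0.10, 0.25, 0.65)),
        "peripheral_vascular_disease": (yes_no, (0.08, 0.92)),
        "chronic_lung_disease": (("No", "Mild", "Moderate", "Severe"),
                                 (0.85, 0.10, 0.04, 0.01)),
        "prior_stroke": (yes_no, (0.04, 0.96)),
        "renal_failure": (yes_no, (0.03, 0.97)),
        "immunosuppression": (yes_no, (0.01, 0.99)),
        "iabp_preop": (yes_no, (0.02, 0.98)),
        "heparin_within_24h": (yes_no, (0.15, 0.85)),
        "smoking_former": (yes_no, (0.35, 0.65)),
        "alcohol_use": (yes_no, (0.05, 0.95)),
    }
    missingness = {
        "BPsystolic": 0.0048,
        "diastolic": 0.0041,
        "pulmonary_artery_done": 0.0041,
        "last_wbc_count": 0.0041,
        "BMI": 0.0041,
        "pulmonary_insufficiency": 0.0041,
    }
    return CohortSpec(
        n_patients=n_patients,
        mode="realistic",
        seed=seed,
        continuous_specs=continuous,
        categorical_specs=categorical,
        missingness=missingness,
    )


def default_truth(n_features: int = 8, n_levels: int = 4, seed: int = 0) -> GroundTruth:
    """Deterministic ground truth for model-faithful cohorts.

    The truth is itself a draw from the hierarchical generative model: a
    scalar coefficient hyper-mean is drawn once and every (level, feature)
    coefficient scatters around it, so partial pooling is correctly
    specified for recovery experiments.

    Two further constraints keep the testbed coherent.  Intercepts are set
    so each level's *effective* mean, ``beta0 + E[x' beta]`` with features
    uniform on [0,1], sits at the bin centre — otherwise a large hyper-mean
    draw pushes means across the bin edge and the bin-consistency rejection
    step visibly distorts the nominal parameters.  The slope scatter (sd 1.2
    days per unit feature) is chosen so coefficients are identifiable at the
    sparsest level the recovery experiments score (~120 records gives a
    per-coefficient standard error near 0.4; recovery checks need effects
    comfortably above that noise floor to probe correctness).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 911)))
    centers = np.array([5.0, 15.0, 25.0, 34.0])[:n_levels]
    mu_b = rng.normal(0.0, 0.5)
    beta = mu_b + rng.normal(0.0, 1.2, size=(n_levels, n_features))
    beta0 = centers - 0.5 * beta.sum(axis=1)
    return GroundTruth(beta0=beta0, beta=beta, sigma=1.0)


def _nbinom_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    if var <= mean:
        raise ValueError("negative binomial requires variance > mean")
    r = mean * mean / (var - mean)
    return r, r / (r + mean)


def _draw_los_components(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Copula-coupled negative-binomial day counts with the published moments."""
    fam1 = spec.continuous_specs["admission_to_surgery"]
    fam2 = spec.continuous_specs["LOS_Surgery_to_discharge"]
    _, m1, s1, lo1, hi1 = fam1
    _, m2, s2, lo2, hi2 = fam2
    r1, p1 = _nbinom_params(m1 - lo1, s1)
    r2, p2 = _nbinom_params(m2 - lo2, s2)
    n = spec.n_patients
    rho = spec.los_copula_rho
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    a = np.empty(n)
    b = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        z = rng.standard_normal((len(todo), 2)) @ chol.T
        u = ndtr(z)
        a_new = lo1 + stats.nbinom.ppf(u[:, 0], r1, p1)
        b_new = lo2 + stats.nbinom.ppf(u[:, 1], r2, p2)
        a[todo], b[todo] = a_new, b_new
        bad = (a[todo] > hi1) | (b[todo] > hi2) | (a[todo] + b[todo] > spec.los_cap) \
            | (a[todo] + b[todo] < 1)
        todo = todo[bad]
        if len(todo) == 0:
            break
    else:  # pragma: no cover - cap rejection essentially never iterates this far
        raise RuntimeError("could not draw LoS components inside the cap")
    return a.astype(int), b.astype(int)


def _truncnorm_rvs(mean, sd, lo, hi, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _generate_realistic(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    n = spec.n_patients
    adm_days, rec_days = _draw_los_components(spec, rng)

    # dates synthesized backwards from the day counts; admissions uniform 2015-2020
    origin = np.datetime64("2015-01-01")
    span = int((np.datetime64("2020-12-31") - origin) / np.timedelta64(1, "D"))
    admission = origin + rng.integers(0, span + 1, size=n).astype("timedelta64[D]")
    surgery = admission + adm_days.astype("timedelta64[D]")
    discharge = surgery + rec_days.astype("timedelta64[D]")

    data: dict[str, np.ndarray] = {
        _ID_COLUMN: np.arange(1, n + 1),
        "date_of_admission": admission,
        "date_of_surgery": surgery,
        "date_of_discharge": discharge,
        "admission_to_surgery": adm_days,
        "LOS_Surgery_to_discharge": rec_days,
    }

    cat_values: dict[str, np.ndarray] = {}
    for name, (labels, probs) in spec.categorical_specs.items():
        codes = rng.choice(len(labels), size=n, p=np.asarray(probs))
        cat_values[name] = np.asarray(labels, dtype=object)[codes]

    hyper = cat_values.get("hypertension")
    for name, fam in spec.continuous_specs.items():
        family, mean, sd, lo, hi = fam
        if name in ("admission_to_surgery", "LOS_Surgery_to_discharge") or family == "derived":
            continue
        if name in spec.bp_conditional and hyper is not None:
            cond = spec.bp_conditional[name]
            out = np.empty(n)
            for label in ("Yes", "No"):
                mask = hyper == label
                out[mask] = _truncnorm_rvs(cond[label], cond["sd"], lo, hi,
                                           int(mask.sum()), rng)
            data[name] = out
        else:
            data[name] = _truncnorm_rvs(mean, sd, lo, hi, n, rng)

    data["BMI"] = data["weight"] / (data["height"] / 100.0) ** 2
    data.update(cat_values)
    frame = pd.DataFrame(data)

    order = ([_ID_COLUMN] + list(_DATE_COLUMNS)
             + [c for c in spec.continuous_specs]
             + [c for c in spec.categorical_specs])
    return frame[order]


def _generate_model_faithful(spec: CohortSpec, rng: np.random.Generator,
                             max_attempts: int = 1000) -> tuple[pd.DataFrame, GroundTruth]:
    truth = spec.truth if spec.truth is not None else default_truth(
        n_features=spec.n_features, n_levels=len(spec.level_proportions), seed=spec.seed)
    n, p = spec.n_patients, truth.beta.shape[1]
    props = np.asarray(spec.level_proportions, dtype=float)[:truth.n_levels]
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("level proportions incompatible with the supplied truth")
    levels = rng.choice(truth.n_levels, size=n, p=props)
    X = rng.uniform(0.0, 1.0, size=(n, p))
    mu = truth.beta0[levels] + np.einsum("ij,ij->i", X, truth.beta[levels])

    edges = np.concatenate([[0.0], LEVEL_EDGES, [np.inf]])
    lo_bin, hi_bin = edges[levels], edges[levels + 1]
    y = np.empty(n)
    if truth.sigma == 0.0:
        y[:] = mu
        if np.any((y < lo_bin) | (y >= hi_bin) | (y < 0)):
            raise ValueError("noiseless mean falls outside the drawn level's bin")
    else:
        todo = np.arange(n)
        for _ in range(max_attempts):
            draw = rng.normal(mu[todo], truth.sigma)
            ok = (draw >= 0) & (draw >= lo_bin[todo]) & (draw < hi_bin[todo])
            y[todo[ok]] = draw[ok]
            todo = todo[~ok]
            if len(todo) == 0:
                break
        else:
            raise RuntimeError(
                f"rejection sampling failed for {len(todo)} records after "
                f"{max_attempts} attempts; level bins unreachable from the truth")

    frame = pd.DataFrame(X, columns=[f"feature_{j}" for j in range(p)])
    frame["LOS"] = y
    truth = GroundTruth(beta0=truth.beta0, beta=truth.beta, sigma=truth.sigma,
                        level_of_record=levels)
    return frame, truth


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth | None]:
    """Generate a cohort table per ``spec``; identical spec+seed gives identical output.

    Returns ``(table, None)`` in realistic mode and ``(table, GroundTruth)``
    in model-faithful mode.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    if spec.mode == "realistic":
        frame = _generate_realistic(spec, rng)
        if spec.missingness:
            frame = inject_missingness(frame, spec.missingness, seed=spec.seed)
        return frame, None
    frame, truth = _generate_model_faithful(spec, rng)
    return frame, truth


def inject_missingness(table: pd.DataFrame, rates: Mapping[str, float],
                       seed: int) -> pd.DataFrame:
    """Set cells missing completely at random at per-column rates."""
    for name in rates:
        if name not in table.columns:
            raise KeyError(f"unknown column for missingness injection: {name!r}")
    out = table.copy()
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    for name, rate in rates.items():
        mask = rng.random(len(out)) < rate
        if mask.any():
            col = out[name]
            if col.dtype.kind in "iu":  # keep integer columns representable
                out[name] = col.astype(float)
            out.loc[mask, name] = np.nan
    return out


# ---------------------------------------------------------------------------
# serialization: CSV table + JSON column dictionary, JSON ground truth

def column_dictionary(spec: CohortSpec) -> dict:
    cols: dict[str, dict] = {_ID_COLUMN: {"type": "identifier"}}
    for name in _DATE_COLUMNS:
        cols[name] = {"type": "date"}
    for name, (family, mean, sd, lo, hi) in spec.continuous_specs.items():
        cols[name] = {"type": "continuous", "family": family, "mean": mean,
                      "sd": sd, "min": lo, "max": hi}
    for name, (labels, probs) in spec.categorical_specs.items():
        cols[name] = {"type": "categorical", "labels": list(labels),
                      "probabilities": [float(x) for x in probs]}
    return cols


def write_cohort(table: pd.DataFrame, out_dir: str | Path,
                 spec: CohortSpec | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "cohort.csv", index=False)
    if spec is not None:
        (out / "columns.json").write_text(
            json.dumps(column_dictionary(spec), indent=1))
    return out / "cohort.csv"


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    # only empty cells are missing; "None" is a legitimate categorical label
    frame = pd.read_csv(path, keep_default_na=False, na_values=[""])
    for name in _DATE_COLUMNS:
        if name in frame.columns:
            frame[name] = pd.to_datetime(frame[name])
    return frame


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "beta0": truth.beta0.tolist(),
        "beta": truth.beta.tolist(),
        "sigma": truth.sigma,
        "level_of_record": (truth.level_of_record.tolist()
                            if truth.level_of_record is not None else None),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        beta0=np.array(payload["beta0"]),
        beta=np.array(payload["beta"]),
        sigma=payload["sigma"],
        level_of_record=(np.array(payload["level_of_record"])
                        if payload["level_of_record"] is not None else None),
    )
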