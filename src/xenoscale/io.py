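"""Reading and writing the pipeline's file formats.

Everything is plain text: tidy CSV for panels, trajectories and survival
curves; YAML for PK specs, regimens and scaling configs; JSON for
population estimates and human distributions.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from xenoscale.pk import ConcentrationProfile, DoseEvent, DoseRegimen, PKModelSpec
from xenoscale.popfit import ErrorModel, PopulationEstimate, TGIStudy
from xenoscale.translate import HumanPopulation, ScalingConfig
from xenoscale.vtrial import SurvivalCurve

__all__ = [
    "load_pk_spec", "default_pk_spec", "load_regimen", "load_regimens",
    "read_panel_csv", "write_panel_csv",
    "write_popest_json", "read_popest_json",
    "write_humanpop_json", "read_humanpop_json",
    "read_survival_csv", "write_survival_csv",
    "read_concentration_csv", "load_scaling_config",
]


def load_pk_spec(path: str | Path) -> PKModelSpec:
    """PK spec from a YAML file (a flat mapping of PKModelSpec fields)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PKModelSpec(**data)


def default_pk_spec(name: str) -> PKModelSpec:
    """One of the packaged default PK specs: mouse_iv, mouse_ip,
    mouse_oral, human_gemcitabine, human_sorafenib."""
    ref = resources.files("xenoscale.data").joinpath("pk_defaults.yaml")
    data = yaml.safe_load(ref.read_text())
    if name not in data:
        raise KeyError(f"unknown PK spec {name!r}; available: {sorted(data)}")
    return PKModelSpec(**data[name])


def load_regimen(path: str | Path) -> DoseRegimen:
    """Regimen from YAML: either a named protocol block
    (protocol/horizon/bsa_m2) or explicit events."""
    from xenoscale.pk import build_regimen

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if "protocol" in data and data["protocol"] != "custom":
        return build_regimen(
            data["protocol"], data["horizon"], bsa_m2=data.get("bsa_m2")
        )
    events = [DoseEvent(**e) for e in data["events"]]
    return DoseRegimen(
        tuple(events), data["horizon"], data.get("time_unit", "day")
    )


def load_regimens(path: str | Path) -> dict[str, DoseRegimen]:
    """Per-study regimens from YAML keyed by study id.

    Each entry gives either explicit ``events`` or a cyclic template:
    ``dose_mg_per_kg`` (with ``bw_kg``, default 0.025) or ``dose_mg``,
    plus ``n_doses``, ``interval_days``, ``route`` and ``horizon``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    out: dict[str, DoseRegimen] = {}
    for sid, block in data.items():
        if "events" in block:
            events = tuple(DoseEvent(**e) for e in block["events"])
            out[str(sid)] = DoseRegimen(
                events, block["horizon"], block.get("time_unit", "day")
            )
            continue
        if "dose_mg" in block:
            amount = float(block["dose_mg"])
        else:
            amount = float(block["dose_mg_per_kg"]) * float(block.get("bw_kg", 0.025))
        interval = float(block.get("interval_days", 3.0))
        n_doses = int(block.get("n_doses", 4))
        horizon = float(block.get("horizon", interval * n_doses + 30.0))
        events = tuple(
            DoseEvent(interval * i, amount, route=block.get("route", "ip"))
            for i in range(n_doses)
            if interval * i < horizon
        )
        out[str(sid)] = DoseRegimen(events, horizon, "day")
    return out


def write_panel_csv(panel: list[TGIStudy], path: str | Path) -> None:
    rows = []
    for s in panel:
        for t, y in zip(s.control_times, s.control_obs):
            rows.append((s.study_id, "control", t, y))
        if s.has_treated:
            for t, y in zip(s.treated_times, s.treated_obs):
                rows.append((s.study_id, "treated", t, y))
    pd.DataFrame(
        rows, columns=["study_id", "arm", "time_day", "tumor_cm3"]
    ).to_csv(path, index=False)


def read_panel_csv(
    path: str | Path, regimens: dict[str, DoseRegimen] | None = None
) -> list[TGIStudy]:
    """Panel from tidy CSV (study_id, arm, time_day, tumor_cm3); regimens,
    when given, are attached by study_id."""
    df = pd.read_csv(path)
    required = {"study_id", "arm", "time_day", "tumor_cm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel CSV must have columns {sorted(required)}")
    studies = []
    for sid, grp in df.groupby("study_id", sort=True):
        ctrl = grp[grp["arm"] == "control"].sort_values("time_day")
        trt = grp[grp["arm"] == "treated"].sort_values("time_day")
        studies.append(
            TGIStudy(
                study_id=str(sid),
                control_times=ctrl["time_day"].to_numpy(),
                control_obs=ctrl["tumor_cm3"].to_numpy(),
                treated_times=trt["time_day"].to_numpy() if len(trt) else None,
                treated_obs=trt["tumor_cm3"].to_numpy() if len(trt) else None,
                regimen=(regimens or {}).get(str(sid)),
            )
        )
    return studies


def write_popest_json(est: PopulationEstimate, path: str | Path) -> None:
    data = est.to_dict()
    data["bootstrap"] = [
        {"theta": b.theta, "omega": b.omega.tolist()} for b in est.bootstrap
    ]
    Path(path).write_text(json.dumps(data, indent=2))


def read_popest_json(path: str | Path) -> PopulationEstimate:
    data = json.loads(Path(path).read_text())
    err = data["error"]
    boot = [
        PopulationEstimate(
            theta=b["theta"], omega=np.array(b["omega"]),
            error=ErrorModel(**err), n_studies=data["n_studies"],
        )
        for b in data.get("bootstrap", [])
    ]
    return PopulationEstimate(
        theta=data["theta"],
        omega=np.array(data["omega"]),
        error=ErrorModel(**err),
        n_studies=data["n_studies"],
        bootstrap=boot,
    )


def write_humanpop_json(pop: HumanPopulation, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "lambda0_pop_per_month": pop.lambda0_pop,
                "k2_pop_L_per_mg_month": pop.k2_pop,
                "omega": pop.omega.tolist(),
            },
            indent=2,
        )
    )


def read_humanpop_json(path: str | Path) -> HumanPopulation:
    data = json.loads(Path(path).read_text())
    return HumanPopulation(
        lambda0_pop=data["lambda0_pop_per_month"],
        k2_pop=data["k2_pop_L_per_mg_month"],
        omega=np.array(data["omega"]),
    )


def write_survival_csv(curve: SurvivalCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_survival_csv(path: str | Path) -> SurvivalCurve:
    """Survival step function from CSV with columns time, survival
    (n_risk/n_event/n_censor optional; right-continuous step convention)."""
    df = pd.read_csv(path, comment="#")
    t = df["time"].to_numpy(dtype=float)
    s = df["survival"].to_numpy(dtype=float)
    zeros = np.zeros_like(t)
    return SurvivalCurve(
        t, s,
        df.get("n_risk", pd.Series(zeros)).to_numpy(dtype=float),
        df.get("n_event", pd.Series(zeros)).to_numpy(dtype=float),
        df.get("n_censor", pd.Series(zeros)).to_numpy(dtype=float),
    )


def read_concentration_csv(
    path: str | Path, time_unit: str = "day"
) -> ConcentrationProfile:
    """Externally supplied exposure profile (e.g. a published concentration
    curve) from a two-column CSV: time, conc_mg_per_L."""
    from xenoscale.pk import cumulative_exposure

    df = pd.read_csv(path, comment="#")
    cols = list(df.columns[:2])
    profile = ConcentrationProfile(
        times=df[cols[0]].to_numpy(dtype=float),
        conc=df[cols[1]].to_numpy(dtype=float),
        time_unit=time_unit,
    )
    return cumulative_exposure(profile)


def load_scaling_config(path: str | Path) -> ScalingConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScalingConfig(**data)
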