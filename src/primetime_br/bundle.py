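"""The input bundle: every table the pipeline consumes, with CSV/YAML I/O.

A bundle mirrors the national data sources the simulation is built on:
beverage consumption and price elasticities (household budget survey),
BMI distribution parameters (national health survey), grouped
epidemiological rates (burden-of-disease estimates), hospital admission
costs, and census population counts.  Bundles are written as a directory
of long-format CSVs plus a ``config.yaml`` so every stage is inspectable
and re-runnable from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agegroups import AGE_GROUPS, expand_to_ages
from .demand import BeverageCategory, ElasticityMatrix
from .disease import AGES, ALL_DISEASES
from .lifetable import DiabetesMediation, RelativeRisk


@dataclass
class InputBundle:
    categories: tuple[BeverageCategory, ...]
    elasticities: dict[str, ElasticityMatrix]      # keyed by income level
    consumption: pd.DataFrame                      # sex, age_group, income, category, volume_ml_day
    bmi: pd.DataFrame                              # sex, age_group, income, mean_bmi, sd_bmi, mean_height_m
    epi_inputs: pd.DataFrame                       # disease, sex, age_group, measure, value
    population: pd.DataFrame                       # sex, age, count
    relative_risks: pd.DataFrame                   # disease, rr_per_5bmi, lo95, hi95
    utilities: pd.DataFrame                        # disease, decrement, sd
    costs: pd.DataFrame                            # disease, sex, age_group, mean_cost_per_admission, sd_cost, admissions_per_case
    mediation: DiabetesMediation = field(default_factory=DiabetesMediation)
    meta: dict = field(default_factory=dict)

    # -- convenience accessors -------------------------------------------

    def population_array(self, sex: str) -> np.ndarray:
        sub = self.population[self.population["sex"] == sex]
        out = np.zeros(len(AGES))
        idx = sub["age"].to_numpy() - AGES[0]
        out[idx] = sub["count"].to_numpy(dtype=float)
        return out

    def relative_risk(self, disease: str, sex: str) -> RelativeRisk:
        row = self.relative_risks[self.relative_risks["disease"] == disease].iloc[0]
        return RelativeRisk(
            disease=disease,
            sex=sex,
            rr_per_5bmi=float(row["rr_per_5bmi"]),
            reference_bmi=float(self.meta.get("tmrel", 22.5)),
            ci=(float(row["lo95"]), float(row["hi95"])),
        )

    def decrements(self) -> dict[str, float]:
        return dict(
            zip(self.utilities["disease"], self.utilities["decrement"].astype(float))
        )

    def cost_per_case(self, sex: str, multipliers: dict[str, float] | None = None) -> dict[str, np.ndarray]:
        """Per-age unit cost arrays (BRL): annual per prevalent case for
        prevalence-based diseases, one-off per incident case otherwise."""
        out = {}
        for d in ALL_DISEASES:
            sub = self.costs[(self.costs["disease"] == d) & (self.costs["sex"] == sex)]
            by_group = {
                g: float(m) * float(a)
                for g, m, a in zip(
                    sub["age_group"], sub["mean_cost_per_admission"],
                    sub["admissions_per_case"],
                )
            }
            missing = set(AGE_GROUPS) - set(by_group)
            if missing:
                raise KeyError(f"cost table incomplete for {d}/{sex}: {sorted(missing)}")
            arr = expand_to_ages(by_group)
            if d == "hhd" and arr.any():
                raise ValueError("hypertensive heart disease costs must be zero")
            mult = 1.0 if multipliers is None else multipliers.get(d, 1.0)
            out[d] = arr * mult
        return out

    # -- disk I/O ---------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {"id": c.id, "name": c.name, "taxed": c.taxed, "kcal_per_ml": c.kcal_per_ml}
                for c in self.categories
            ]
        ).to_csv(path / "categories.csv", index=False)
        rows = []
        for income, mat in self.elasticities.items():
            for i, ri in enumerate(mat.category_ids):
                for j, cj in enumerate(mat.category_ids):
                    rows.append(
                        {"stratum": income, "row_category": ri, "col_category": cj,
                         "value": mat.values[i, j]}
                    )
        pd.DataFrame(rows).to_csv(path / "elasticities.csv", index=False)
        self.consumption.to_csv(path / "consumption.csv", index=False)
        self.bmi.to_csv(path / "bmi_baseline.csv", index=False)
        self.epi_inputs.to_csv(path / "epi_inputs.csv", index=False)
        self.population.to_csv(path / "population.csv", index=False)
        self.relative_risks.to_csv(path / "rr.csv", index=False)
        self.utilities.to_csv(path / "utility.csv", index=False)
        self.costs.to_csv(path / "costs.csv", index=False)
        cfg = dict(self.meta)
        cfg["mediation"] = {
            "rr_ihd_given_dm": self.mediation.rr_ihd_given_dm,
            "rr_stroke_given_dm": self.mediation.rr_stroke_given_dm,
            "ci_ihd": list(self.mediation.ci_ihd) if self.mediation.ci_ihd else None,
            "ci_stroke": list(self.mediation.ci_stroke) if self.mediation.ci_stroke else None,
        }
        (path / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))

    @classmethod
    def from_dir(cls, path: str | Path) -> "InputBundle":
        path = Path(path)
        cats = tuple(
            BeverageCategory(int(r.id), str(r.name), bool(r.taxed), float(r.kcal_per_ml))
            for r in pd.read_csv(path / "categories.csv").itertuples()
        )
        edf = pd.read_csv(path / "elasticities.csv")
        elas = {}
        ids = sorted(edf["row_category"].unique())
        for income, sub in edf.groupby("stratum"):
            mat = (
                sub.pivot(index="row_category", columns="col_category", values="value")
                .loc[ids, ids]
                .to_numpy()
            )
            elas[str(income)] = ElasticityMatrix(mat, stratum=str(income), category_ids=tuple(ids))
        cfg = yaml.safe_load((path / "config.yaml").read_text())
        med_cfg = cfg.pop("mediation", {})
        mediation = DiabetesMediation(
            rr_ihd_given_dm=float(med_cfg.get("rr_ihd_given_dm", 2.0)),
            rr_stroke_given_dm=float(med_cfg.get("rr_stroke_given_dm", 1.8)),
            ci_ihd=tuple(med_cfg["ci_ihd"]) if med_cfg.get("ci_ihd") else None,
            ci_stroke=tuple(med_cfg["ci_stroke"]) if med_cfg.get("ci_stroke") else None,
        )
        return cls(
            categories=cats,
            elasticities=elas,
            consumption=pd.read_csv(path / "consumption.csv"),
            bmi=pd.read_csv(path / "bmi_baseline.csv"),
            epi_inputs=pd.read_csv(path / "epi_inputs.csv"),
            population=pd.read_csv(path / "population.csv"),
            relative_risks=pd.read_csv(path / "rr.csv"),
            utilities=pd.read_csv(path / "utility.csv"),
            costs=pd.read_csv(path / "costs.csv"),
            mediation=mediation,
            meta=cfg,
        )
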