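"""Plain-text serialization: parameter configs, kinetics tables, grids."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_model import EnzymeKinetics, GrowthLaw, ModelParams

__all__ = [
    "params_to_yaml",
    "params_from_yaml",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "grid_to_csv",
    "grid_from_csv",
]


def params_to_yaml(params: ModelParams, path) -> None:
    """Write a ModelParams config losslessly round-trippable by YAML."""
    doc = {
        "growth_law": {
            "g_max": float(params.growth_law.g_max),
            "g_min": float(params.growth_law.g_min),
            "K": float(params.growth_law.K),
            "n": float(params.growth_law.n),
        },
        "dhfr_conc": float(params.dhfr_conc),
        "fol_tot": float(params.fol_tot),
        "thf_scale": float(params.thf_scale),
        "tyms_concs": {k: float(v) for k, v in params.tyms_concs.items()},
        "tyms_kinetics": {
            k: {"kcat": float(v.kcat), "km": float(v.km)}
            for k, v in params.tyms_kinetics.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def params_from_yaml(path) -> ModelParams:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ModelParams(
        growth_law=GrowthLaw(**doc["growth_law"]),
        dhfr_conc=doc["dhfr_conc"],
        tyms_concs=doc["tyms_concs"],
        fol_tot=doc["fol_tot"],
        thf_scale=doc.get("thf_scale", 1.0),
        tyms_kinetics={
            k: EnzymeKinetics(**v) for k, v in doc.get("tyms_kinetics", {}).items()
        },
    )


def read_kinetics_csv(path) -> dict[tuple[str, str], EnzymeKinetics]:
    """Read a variant kinetics table: variant, enzyme, kcat_per_s, km_uM.

    Replicate rows for the same (variant, enzyme) are averaged.
    """
    df = pd.read_csv(path)
    out = {}
    for (variant, enzyme), grp in df.groupby(["variant", "enzyme"]):
        out[(str(variant), str(enzyme))] = EnzymeKinetics(
            kcat=float(grp["kcat_per_s"].mean()), km=float(grp["km_uM"].mean())
        )
    return out


def write_kinetics_csv(
    kinetics: Mapping[tuple[str, str], EnzymeKinetics], path
) -> None:
    rows = [
        {
            "variant": variant,
            "enzyme": enzyme,
            "kcat_per_s": kin.kcat,
            "km_uM": kin.km,
        }
        for (variant, enzyme), kin in kinetics.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def grid_to_csv(
    matrix: np.ndarray,
    row_values: Sequence[float],
    col_values: Sequence[float],
    path,
    row_label: str = "kcat",
    col_label: str = "km",
) -> None:
    """Export a landscape matrix as CSV with axis headers."""
    df = pd.DataFrame(matrix, index=row_values, columns=col_values)
    df.index.name = f"{row_label}\\{col_label}"
    df.to_csv(path)


def grid_from_csv(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a grid CSV back: (matrix, row_values, col_values)."""
    df = pd.read_csv(path, index_col=0)
    return (
        df.to_numpy(float),
        df.index.to_numpy(float),
        df.columns.to_numpy(float),
    )
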