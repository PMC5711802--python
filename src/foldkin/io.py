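"""Reading and writing the package's delimited-text dialects.

Every dataset travels as a plain CSV with a header row and optional
``# key=value`` comment lines carrying metadata, matching what CD and
stopped-flow instruments export:

* denaturation curve: ``perturbation,signal[,sigma]`` with
  ``# probe=``, ``# mode=``, ``# pH=``, ``# ionic_strength=``,
  ``# temperature=``;
* kinetic transient: ``time,signal`` with ``# experiment=``,
  ``# final_urea=``, ``# c_N_premix=``, ``# mix_ratio=1:11``;
* chevron: ``urea,k_obs[,sigma]`` with ``# temperature=``;
* salt series: ``ionic_strength,dG[,dG_sigma]`` or
  ``ionic_strength,Tm,dHm``.

Readers report malformed rows with their line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .association import c_N_from_premix
from .datasets import (
    ChevronDataset,
    Condition,
    DenaturationCurve,
    KineticTransient,
    SaltSeries,
    TransientMeta,
)
from .exceptions import InvalidInputError

__all__ = [
    "read_curve",
    "read_transient",
    "read_chevron",
    "read_series",
    "write_curve",
    "write_transient",
    "write_chevron",
    "write_series",
    "write_result_json",
    "parse_mix_ratio",
]


def parse_mix_ratio(text: str) -> tuple[int, int]:
    """Parse a volumetric mixing ratio like ``1:11``."""
    try:
        a, b = (int(part) for part in text.split(":"))
    except Exception:
        raise InvalidInputError(f"malformed mix ratio {text!r}") from None
    return a, b


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    """Parse a metadata-commented CSV into a numeric frame + meta dict."""
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                continue
            if len(cells) != len(header):
                raise InvalidInputError(
                    f"{path.name}:{lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                raise InvalidInputError(
                    f"{path.name}:{lineno}: non-numeric cell in {cells!r}"
                ) from None
    if header is None or not rows:
        raise InvalidInputError(f"{path.name}: no data rows found")
    return pd.DataFrame(rows, columns=header), meta


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{Path(path).name}: missing required columns {missing}")


def read_curve(path) -> tuple[DenaturationCurve, dict]:
    """Read one equilibrium denaturation curve; returns (curve, meta)."""
    df, meta = _read_table(path)
    _require(df, ["perturbation", "signal"], path)
    condition = Condition(
        pH=float(meta["pH"]) if "pH" in meta else None,
        ionic_strength=float(meta["ionic_strength"]) if "ionic_strength" in meta else None,
        label=meta.get("label", ""),
    )
    curve = DenaturationCurve(
        perturbation=df["perturbation"].to_numpy(),
        signal=df["signal"].to_numpy(),
        probe=meta.get("probe", "CD222"),
        mode=meta.get("mode", "chemical"),
        condition=condition,
        sigma=df["sigma"].to_numpy() if "sigma" in df.columns else None,
    )
    return curve, meta


def read_transient(path) -> tuple[KineticTransient, dict]:
    """Read one stopped-flow transient; returns (transient, meta).

    For association experiments with ``c_N_premix`` and ``mix_ratio``
    metadata, the post-mixing monomer concentration is computed and
    stored in ``meta['c_N']``.
    """
    df, meta = _read_table(path)
    _require(df, ["time", "signal"], path)
    time = df["time"].to_numpy()
    if len(np.unique(time)) != len(time):
        dup = time[np.concatenate([[False], np.diff(time) == 0])][0]
        raise InvalidInputError(f"{Path(path).name}: duplicate time stamp t={dup}")
    transient = KineticTransient(
        time=time,
        signal=df["signal"].to_numpy(),
        meta=TransientMeta(
            experiment=meta.get("experiment", "folding"),
            final_urea=float(meta["final_urea"]) if "final_urea" in meta else None,
            label=meta.get("label", ""),
        ),
    )
    if "c_N_premix" in meta and "mix_ratio" in meta:
        meta["c_N"] = str(
            c_N_from_premix(float(meta["c_N_premix"]), parse_mix_ratio(meta["mix_ratio"]))
        )
    return transient, meta


def read_chevron(path) -> tuple[ChevronDataset, dict]:
    """Read a chevron table (urea, k_obs[, sigma])."""
    df, meta = _read_table(path)
    _require(df, ["urea", "k_obs"], path)
    data = ChevronDataset(
        urea=df["urea"].to_numpy(),
        k_obs=df["k_obs"].to_numpy(),
        temperature=float(meta.get("temperature", 298.0)),
        sigma=df["sigma"].to_numpy() if "sigma" in df.columns else None,
    )
    return data, meta


def read_series(path) -> tuple[SaltSeries, dict]:
    """Read a salt series, either (I, dG[, dG_sigma]) or (I, Tm, dHm)."""
    df, meta = _read_table(path)
    _require(df, ["ionic_strength"], path)
    if "dG" in df.columns:
        series = SaltSeries(
            ionic_strength=df["ionic_strength"].to_numpy(),
            dG=df["dG"].to_numpy(),
            source="chemical",
            label=meta.get("label", ""),
        )
    elif "Tm" in df.columns and "dHm" in df.columns:
        series = SaltSeries(
            ionic_strength=df["ionic_strength"].to_numpy(),
            T_m=df["Tm"].to_numpy(),
            dH_m=df["dHm"].to_numpy(),
            source="thermal",
            label=meta.get("label", ""),
        )
    else:
        raise InvalidInputError(
            f"{Path(path).name}: need either a dG column or Tm and dHm columns"
        )
    return series, meta


def _write_table(path, meta: dict, frame: pd.DataFrame) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in meta.items():
            if value is not None and value != "":
                fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, index=False)


def write_curve(path, curve: DenaturationCurve, extra_meta: dict | None = None) -> None:
    meta = {
        "probe": curve.probe.value,
        "mode": curve.mode.value,
        "pH": curve.condition.pH,
        "ionic_strength": curve.condition.ionic_strength,
        "label": curve.condition.label,
    }
    meta.update(extra_meta or {})
    cols = {"perturbation": curve.perturbation, "signal": curve.signal}
    if curve.sigma is not None:
        cols["sigma"] = curve.sigma
    _write_table(path, meta, pd.DataFrame(cols))


def write_transient(path, tr: KineticTransient, extra_meta: dict | None = None) -> None:
    meta = {
        "experiment": tr.meta.experiment.value,
        "final_urea": tr.meta.final_urea,
        "label": tr.meta.label,
    }
    meta.update(extra_meta or {})
    _write_table(path, meta, pd.DataFrame({"time": tr.time, "signal": tr.signal}))


def write_chevron(path, data: ChevronDataset, extra_meta: dict | None = None) -> None:
    meta = {"temperature": data.temperature}
    meta.update(extra_meta or {})
    cols = {"urea": data.urea, "k_obs": data.k_obs}
    if data.sigma is not None:
        cols["sigma"] = data.sigma
    _write_table(path, meta, pd.DataFrame(cols))


def write_series(path, series: SaltSeries, extra_meta: dict | None = None) -> None:
    meta = {"label": series.label, "source": series.source.value}
    meta.update(extra_meta or {})
    if series.dG is not None:
        frame = pd.DataFrame({"ionic_strength": series.ionic_strength, "dG": series.dG})
    else:
        frame = pd.DataFrame(
            {"ionic_strength": series.ionic_strength, "Tm": series.T_m,
             "dHm": series.dH_m}
        )
    _write_table(path, meta, frame)


def write_result_json(path, result, extra: dict | None = None) -> None:
    """Serialize a fit result (anything with .to_dict()) to JSON."""
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    if extra:
        payload = {**payload, **extra}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
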