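"""File formats and model persistence.

Expression matrices are delimited text (TSV or CSV, auto-detected):
variables in rows, samples in columns, a header row of sample IDs and the
first column holding variable IDs.  Labels are a two-column table mapping
sample ID to an arbitrary class label; labels are mapped to the internal
1..K coding in sorted order and the mapping is persisted with the model.

Fitted models round-trip through a versioned, checksummed JSON container so
that predictions from a reloaded model are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CentroidStatistics, ExpressionData
from .shrinkage import ShrinkageSpec, ShrunkenModel
from .tuning import ThresholdGrid, TuningResult

__all__ = ["RunConfig", "read_expression", "write_expression", "read_labels",
           "save_model", "load_model", "read_scenario_config",
           "write_scenario_config"]

MODEL_FORMAT = "gmnsc-model"
MODEL_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to reproduce one training run."""

    method: str = "pam"
    criterion: str = "max_gmeans"
    T: int = 30
    spacing: str = "linear"
    folds: int = 10
    priors_mode: str = "equal"
    fold_seed: int = 0
    tie_seed: int = 0
    sim_seed: int = 0
    matrix_path: str | None = None
    labels_path: str | None = None
    output_path: str | None = None
    verbosity: int = 1
    label_mapping: dict = field(default_factory=dict)  # external -> 1..K

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_labels(path: str) -> dict[str, str]:
    """Sample ID -> class label from a two-column delimited file.

    A header line is accepted (and skipped) when its second field does not
    reappear as a class among the remaining rows of a two-class-or-more file;
    files written by :func:`write_labels`-style tools with the header
    ``sample_id<TAB>class`` are the expected form.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_expression(path: str, labels_path: str,
                    transpose: bool = False) -> tuple[ExpressionData, dict]:
    """Load a variables-by-samples matrix and join class labels by sample ID.

    Returns ``(data, label_mapping)`` with external labels mapped to 1..K in
    sorted order.  ``transpose`` reads a samples-by-variables layout.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0,
                     float_precision="round_trip")
    if transpose:
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate variable ID {dup!r} in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    sample_ids = [str(c) for c in df.columns]
    labels_by_id = read_labels(labels_path)
    missing = [s for s in sample_ids if s not in labels_by_id]
    if missing:
        raise ValueError(
            f"labels file {labels_path} is missing sample(s): {missing[:5]}")
    raw = [labels_by_id[s] for s in sample_ids]
    classes = sorted(set(raw))
    mapping = {c: k + 1 for k, c in enumerate(classes)}
    labels = np.array([mapping[c] for c in raw])
    data = ExpressionData(values=values,
                          variable_ids=[str(v) for v in df.index],
                          sample_ids=sample_ids, labels=labels)
    return data, mapping


def write_expression(data: ExpressionData, path: str, sep: str = "\t") -> None:
    df = pd.DataFrame(data.values, index=data.variable_ids,
                      columns=data.sample_ids)
    # %.17g guarantees a bit-identical float round trip through text
    df.to_csv(path, sep=sep, float_format="%.17g")


# ---------------------------------------------------------------------------
# model container

def _arr(a) -> list:
    return np.asarray(a).tolist()


def _payload_checksum(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def save_model(model: ShrunkenModel, path: str,
               tuning: TuningResult | None = None,
               config: RunConfig | None = None) -> None:
    """Serialize a fitted model (plus tuning trace and run config) to JSON."""
    stats = model.stats
    spec = model.spec
    payload = {
        "spec": {
            "method": spec.method,
            "threshold": spec.threshold,
            "alp_weights": _arr(spec.alp_weights)
                if spec.alp_weights is not None else None,
            "ahp_weights_gamma": _arr(spec.ahp_weights_gamma)
                if spec.ahp_weights_gamma is not None else None,
            "ahp_weights_theta": _arr(spec.ahp_weights_theta)
                if spec.ahp_weights_theta is not None else None,
            "ahp_lambda_link": spec.ahp_lambda_link,
        },
        "d_hat": _arr(model.d_hat),
        "active": _arr(model.active.astype(int)),
        "stats": {
            "class_centroids": _arr(stats.class_centroids),
            "overall_centroid": _arr(stats.overall_centroid),
            "pooled_sd": _arr(stats.pooled_sd),
            "s0": stats.s0,
            "m": _arr(stats.m),
            "d": _arr(stats.d),
            "class_counts": _arr(stats.class_counts),
            "n": stats.n,
        },
        "tuning": None,
        "config": config.to_dict() if config is not None else None,
    }
    if tuning is not None:
        payload["tuning"] = {
            "grid_values": _arr(tuning.grid.values),
            "spacing": tuning.grid.spacing,
            "cv_error": _arr(tuning.cv_error),
            "cv_pa": _arr(tuning.cv_pa),
            "cv_gmeans": _arr(tuning.cv_gmeans),
            "mean_active": _arr(tuning.mean_active),
            "folds": tuning.folds,
            "fold_seed": tuning.fold_seed,
            "criterion": tuning.criterion,
            "selected_threshold": tuning.selected_threshold,
        }
    container = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "sha256": _payload_checksum(payload),
        "payload": payload,
    }
    with open(path, "w") as fh:
        json.dump(container, fh, indent=1)


def load_model(path: str):
    """Inverse of :func:`save_model`.

    Returns ``(model, tuning, config)``; tuning/config are None when absent.
    Raises on format/version mismatch or checksum failure.
    """
    with open(path) as fh:
        container = json.load(fh)
    if container.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path} is not a {MODEL_FORMAT} file")
    if container.get("version") != MODEL_VERSION:
        raise ValueError(
            f"model version {container.get('version')} unsupported "
            f"(expected {MODEL_VERSION})")
    payload = container["payload"]
    if _payload_checksum(payload) != container.get("sha256"):
        raise ValueError(f"checksum mismatch: {path} is corrupted")
    st = payload["stats"]
    stats = CentroidStatistics(
        class_centroids=np.array(st["class_centroids"]),
        overall_centroid=np.array(st["overall_centroid"]),
        pooled_sd=np.array(st["pooled_sd"]),
        s0=float(st["s0"]),
        m=np.array(st["m"]),
        d=np.array(st["d"]),
        class_counts=np.array(st["class_counts"]),
        n=int(st["n"]),
    )
    sp = payload["spec"]
    spec = ShrinkageSpec(
        method=sp["method"], threshold=sp["threshold"],
        alp_weights=np.array(sp["alp_weights"])
            if sp["alp_weights"] is not None else None,
        ahp_weights_gamma=np.array(sp["ahp_weights_gamma"])
            if sp["ahp_weights_gamma"] is not None else None,
        ahp_weights_theta=np.array(sp["ahp_weights_theta"])
            if sp["ahp_weights_theta"] is not None else None,
        ahp_lambda_link=sp["ahp_lambda_link"],
    )
    d_hat = np.array(payload["d_hat"])
    from .core import shrunken_centroids
    model = ShrunkenModel(
        spec=spec, d_hat=d_hat,
        shrunken_centroids=shrunken_centroids(stats, d_hat),
        active=np.array(payload["active"], dtype=bool),
        stats=stats,
    )
    tuning = None
    if payload.get("tuning") is not None:
        tu = payload["tuning"]
        tuning = TuningResult(
            grid=ThresholdGrid(values=np.array(tu["grid_values"]),
                               spacing=tu["spacing"]),
            cv_error=np.array(tu["cv_error"]),
            cv_pa=np.array(tu["cv_pa"]),
            cv_gmeans=np.array(tu["cv_gmeans"]),
            mean_active=np.array(tu["mean_active"]),
            folds=tu["folds"], fold_seed=tu["fold_seed"],
            criterion=tu["criterion"],
            selected_threshold=tu["selected_threshold"],
        )
    config = None
    if payload.get("config") is not None:
        config = RunConfig.from_dict(payload["config"])
    return model, tuning, config


# ---------------------------------------------------------------------------
# scenario config (flat key=value text)

def write_scenario_config(params: dict, path: str) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"{k}={v}\n")


def read_scenario_config(path: str) -> dict:
    """Flat key=value file with int/float/bool coercion."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            k, v = line.split("=", 1)
            k, v = k.strip(), v.strip()
            if v.lower() in ("true", "false"):
                out[k] = v.lower() == "true"
            else:
                try:
                    out[k] = int(v)
                except ValueError:
                    try:
                        out[k] = float(v)
                    except ValueError:
                        out[k] = v
    return out
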