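"""Tidy-text serialization of results with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .config import AppConfig, config_hash

__all__ = ["write_traces", "read_events", "write_manifest"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"   # 12 significant digits


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_traces(result, out_dir: str | Path,
                 config: AppConfig | None = None) -> dict[str, str]:
    """Write an :class:`~hsmtd.pipeline.ExperimentResult` as tidy tabular
    text plus a JSON manifest; returns the file-checksum inventory."""
    out_dir = Path(out_dir)
    if not out_dir.exists():
        out_dir.mkdir(parents=True)
        log.info("created output directory %s", out_dir)
    files: dict[str, str] = {}
    try:
        events_path = out_dir / "events.csv"
        result.events.to_csv(events_path, index=False, float_format=_FLOAT_FMT)
        files["events.csv"] = _sha256(events_path)
        if result.traces is not None:
            rows = []
            for sim, session, delta, _events in result.traces:
                rows.append(pd.DataFrame({"sim": sim, "session": session,
                                          "t": range(len(delta)),
                                          "delta_total": delta}))
            traces_path = out_dir / "delta_traces.csv"
            pd.concat(rows, ignore_index=True).to_csv(
                traces_path, index=False, float_format=_FLOAT_FMT)
            files["delta_traces.csv"] = _sha256(traces_path)
    except OSError as exc:
        raise OSError(f"failed writing results under {out_dir}: {exc}") from exc
    write_manifest(out_dir, result, files, config)
    return files


def write_manifest(out_dir: Path, result, files: dict[str, str],
                   config: AppConfig | None) -> None:
    import hsmtd
    manifest = {
        "model_kind": result.model_kind,
        "lesion_kind": result.lesion_kind,
        "seeds": list(result.seeds),
        "config_hash": config_hash(config) if config is not None else None,
        "version": getattr(hsmtd, "__version__", "unknown"),
        "files": files,
    }
    (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_events(out_dir: str | Path) -> pd.DataFrame:
    """Read back the tidy event table written by :func:`write_traces`."""
    return pd.read_csv(Path(out_dir) / "events.csv")
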