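"""Delimited-text trace formats and the deterministic results bundle.

Traces are plain CSV with a header row, '.' decimal, and '#'-prefixed
``key = value`` metadata lines before the header:

* MIMS traces: columns ``time_s, mz34, mz36[, mz32]``; required metadata
  ``injection_time_s``; optional provenance (enrichments, protocol, seed,
  ground truth) round-trips through the metadata block.
* Fluorescence traces: columns ``time_s, fv``; optional metadata ``f0`` and
  ``fmax`` mark a raw (unnormalized) trace.

Results are written as a diff-stable text bundle: fixed column order, rates to
3 significant figures, an explicit ``not_estimated`` marker where an
uncertainty is unavailable, and a provenance block (config hash, seed,
package version) — never timestamps, so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .synthetic import FluorTrace, MimsTrace

__all__ = ["ResultsBundle", "read_trace", "write_trace", "write_results"]

_META_FLOAT_KEYS = {
    "injection_time_s", "alpha_i", "alpha_f", "flash_frequency", "t_s3",
    "k_f_s3", "mixing_tau", "residual_o2_step", "noise_sigma",
    "scale_34", "scale_36", "truth_k_f", "truth_k_s", "f0", "fmax",
    "baseline_noise_34", "baseline_noise_36",
    "residual_step_34", "residual_step_36",
}
_META_INT_KEYS = {"seed"}
_META_BOOL_KEYS = {"synthetic", "preprocessed"}


class TraceParseError(ValueError):
    """Malformed trace file (bad cell, missing column, bad metadata)."""


def _parse_meta_lines(path: Path) -> Dict[str, object]:
    meta: Dict[str, object] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if not body or "=" not in body:
                continue
            key, _, value = body.partition("=")
            key, value = key.strip(), value.strip()
            if value == "" or value.lower() == "none":
                meta[key] = None
            elif key in _META_FLOAT_KEYS:
                try:
                    meta[key] = float(value)
                except ValueError as exc:
                    raise TraceParseError(
                        f"{path}:{lineno}: metadata {key!r} is not numeric: {value!r}"
                    ) from exc
            elif key in _META_INT_KEYS:
                meta[key] = int(float(value))
            elif key in _META_BOOL_KEYS:
                meta[key] = value.lower() in ("1", "true", "yes")
            else:
                meta[key] = value
    return meta


def _read_numeric_frame(path: Path, required: List[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    except Exception as exc:
        raise TraceParseError(f"{path}: cannot parse CSV: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceParseError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col].str.strip(), errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise TraceParseError(
                f"{path}: malformed numeric cell in column {col!r}, data row "
                f"{row + 1}: {df[col].iloc[row]!r}"
            )
        if converted.isna().any():
            row = int(converted.isna().idxmax())
            raise TraceParseError(
                f"{path}: empty cell in column {col!r}, data row {row + 1}"
            )
        out[col] = converted.astype(float)
    return out


def read_trace(
    path: Union[str, Path], kind: str = "mims"
) -> Union[MimsTrace, FluorTrace]:
    """Read a MIMS or fluorescence trace from delimited text.

    Validates column presence, numeric cells (errors carry the data row
    number), strictly increasing time, and finite values.
    """
    path = Path(path)
    meta = _parse_meta_lines(path)
    if kind == "mims":
        df = _read_numeric_frame(path, ["time_s", "mz34", "mz36"])
        injection = meta.get("injection_time_s")
        if injection is None:
            raise TraceParseError(
                f"{path}: metadata line '# injection_time_s = <s>' is required"
            )
        t = df["time_s"].to_numpy()
        _check_time(path, t)
        return MimsTrace(
            t=t,
            y34=df["mz34"].to_numpy(),
            y36=df["mz36"].to_numpy(),
            y32=df["mz32"].to_numpy() if "mz32" in df.columns else None,
            injection_time=float(injection),
            meta={k: v for k, v in meta.items() if k != "injection_time_s"},
        )
    if kind == "fluor":
        df = _read_numeric_frame(path, ["time_s", "fv"])
        t = df["time_s"].to_numpy()
        _check_time(path, t)
        f0 = meta.pop("f0", None)
        fmax = meta.pop("fmax", None)
        return FluorTrace(t=t, fv=df["fv"].to_numpy(), f0=f0, fmax=fmax, meta=meta)
    raise ValueError(f"unknown trace kind {kind!r} (expected 'mims' or 'fluor')")


def _check_time(path: Path, t: np.ndarray) -> None:
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise TraceParseError(
            f"{path}: time_s not strictly increasing at data row {int(bad[0]) + 2}"
        )


def write_trace(trace: Union[MimsTrace, FluorTrace], path: Union[str, Path]) -> None:
    """Write a trace as CSV with a '#' metadata block (round-trips to 1e-12)."""
    path = Path(path)
    lines: List[str] = []
    if isinstance(trace, MimsTrace):
        lines.append(f"# injection_time_s = {trace.injection_time!r}")
        meta = trace.meta
        columns = {"time_s": trace.t, "mz34": trace.y34, "mz36": trace.y36}
        if trace.y32 is not None:
            columns["mz32"] = trace.y32
    else:
        meta = dict(trace.meta)
        if trace.f0 is not None:
            meta["f0"] = trace.f0
        if trace.fmax is not None:
            meta["fmax"] = trace.fmax
        columns = {"time_s": trace.t, "fv": trace.fv}
    for key in sorted(meta):
        value = meta[key]
        if isinstance(value, dict):
            continue
        lines.append(f"# {key} = {value if value is not None else 'none'}")
    lines.append(",".join(columns))
    arrays = list(columns.values())
    for row in zip(*arrays):
        lines.append(",".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# Results bundle

_NOT_ESTIMATED = "not_estimated"


@dataclass
class ResultsBundle:
    """Parameter tables plus provenance for one analysis run.

    ``exchange_rows``: dicts with keys sample, state, k_f, k_s, optional
    k_f_se / k_s_se, converged.  ``fluorescence_rows``: dicts with keys
    sample, tau1..tau3, amp1..amp3 (percent), optional *_se, converged.
    Every estimate is written with its uncertainty or an explicit
    ``not_estimated`` marker.
    """

    exchange_rows: List[Dict] = field(default_factory=list)
    fluorescence_rows: List[Dict] = field(default_factory=list)
    provenance: Dict[str, object] = field(default_factory=dict)

    @staticmethod
    def config_hash(config_text: str) -> str:
        return hashlib.sha256(config_text.encode("utf-8")).hexdigest()[:12]


def _sig3(value: Optional[float]) -> str:
    if value is None or (isinstance(value, float) and not math.isfinite(value)):
        return _NOT_ESTIMATED
    return f"{value:.3g}"


def write_results(bundle: ResultsBundle, path: Union[str, Path]) -> None:
    """Write a deterministic, diff-stable results file.

    Fixed section and column order; rates and uncertainties to 3 significant
    figures; no timestamps — the same bundle always produces byte-identical
    output.
    """
    path = Path(path)
    lines: List[str] = ["# mimsfit results"]
    for key in sorted(bundle.provenance):
        lines.append(f"# {key} = {bundle.provenance[key]}")
    if bundle.exchange_rows:
        lines.append("[exchange]")
        lines.append("sample,state,k_f_per_s,k_f_se,k_s_per_s,k_s_se,converged")
        for row in bundle.exchange_rows:
            lines.append(
                ",".join(
                    [
                        str(row.get("sample", "sample")),
                        str(row.get("state", "?")),
                        _sig3(row.get("k_f")),
                        _sig3(row.get("k_f_se")),
                        _sig3(row.get("k_s")),
                        _sig3(row.get("k_s_se")),
                        "yes" if row.get("converged", False) else "no",
                    ]
                )
            )
    if bundle.fluorescence_rows:
        lines.append("[fluorescence]")
        header = ["sample"]
        for i in (1, 2, 3):
            header += [f"tau{i}_s", f"tau{i}_se", f"halftime{i}_s", f"amp{i}_pct"]
        header += ["a0", "converged"]
        lines.append(",".join(header))
        for row in bundle.fluorescence_rows:
            cells = [str(row.get("sample", "sample"))]
            for i in (1, 2, 3):
                tau = row.get(f"tau{i}")
                cells += [
                    _sig3(tau),
                    _sig3(row.get(f"tau{i}_se")),
                    _sig3(tau * math.log(2.0) if tau is not None else None),
                    _sig3(row.get(f"amp{i}")),
                ]
            cells.append(_sig3(row.get("a0")))
            cells.append("yes" if row.get("converged", False) else "no")
            lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
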