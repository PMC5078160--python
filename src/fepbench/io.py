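"""Readers and writers for the package's tabular interchange formats.

All formats are plain text:

* **window file** — TSV with columns ``lambda_low, lambda_high, direction
  (fwd|rev), dU``; one row per perturbation-energy sample.  An optional
  companion TSV (``lambda, dudl``) supplies dU/dlambda samples keyed by
  coupling value.
* **u_kn file** — CSV whose first column is each snapshot's origin-state
  index and remaining columns the potential evaluated at every state; a
  structured-text header of ``#``-prefixed YAML lines carries the lambda
  schedule and temperature, making the file self-describing.
* **edge / ligand / component / pairs CSVs** — thin wrappers around the
  in-memory types of the network, qmscore, and metrics modules.

Malformed rows are reported with their 1-based line numbers.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import ReducedPotentialSet, WindowSamples
from .exceptions import InputError
from .metrics import AffinityPairs
from .network import (
    EdgeCandidate,
    Ligand,
    PerturbationEdge,
    PerturbationNetwork,
)
from .qmscore import EnergyComponents, VibrationalModes

__all__ = [
    "read_window_file",
    "write_window_file",
    "read_dudl_file",
    "read_ukn_file",
    "write_ukn_file",
    "read_network",
    "read_components",
    "read_pairs",
    "read_frequencies",
]

_WINDOW_COLUMNS = ("lambda_low", "lambda_high", "direction", "dU")


def read_window_file(path, dudl_path=None) -> list[WindowSamples]:
    """Parse a window TSV into validated :class:`WindowSamples`.

    Rows are grouped by (lambda_low, lambda_high); ``fwd`` rows populate
    the forward samples, ``rev`` rows the backward ones.  Any missing
    column, non-numeric or non-finite cell, or unknown direction raises
    :class:`InputError` naming the offending line.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if not text:
        raise InputError(f"{path}: empty file")
    header = text[0].rstrip("\n").split("\t")
    missing = [c for c in _WINDOW_COLUMNS if c not in header]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in _WINDOW_COLUMNS}
    groups: dict[tuple[float, float], dict[str, list[float]]] = {}
    for lineno, line in enumerate(text[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) < len(header):
            raise InputError(f"{path}:{lineno}: expected {len(header)} cells")
        try:
            lo = float(cells[idx["lambda_low"]])
            hi = float(cells[idx["lambda_high"]])
            du = float(cells[idx["dU"]])
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        if not (math.isfinite(lo) and math.isfinite(hi) and math.isfinite(du)):
            raise InputError(f"{path}:{lineno}: non-finite value")
        direction = cells[idx["direction"]].strip()
        if direction not in ("fwd", "rev"):
            raise InputError(
                f"{path}:{lineno}: direction must be fwd or rev, got "
                f"{direction!r}"
            )
        groups.setdefault((lo, hi), {"fwd": [], "rev": []})[direction].append(du)
    if not groups:
        raise InputError(f"{path}: no data rows")

    dudl = read_dudl_file(dudl_path) if dudl_path is not None else {}
    windows = []
    for (lo, hi) in sorted(groups):
        data = groups[(lo, hi)]
        windows.append(WindowSamples(
            lambda_low=lo, lambda_high=hi,
            dU_forward=np.asarray(data["fwd"]),
            dU_backward=np.asarray(data["rev"]),
            dudl_low=dudl.get(lo), dudl_high=dudl.get(hi),
        ))
    return windows


def write_window_file(path, windows: list[WindowSamples]) -> None:
    path = Path(path)
    lines = ["\t".join(_WINDOW_COLUMNS)]
    for w in windows:
        for direction, samples in (("fwd", w.dU_forward), ("rev", w.dU_backward)):
            for du in samples:
                lines.append(
                    f"{float(w.lambda_low)!r}\t{float(w.lambda_high)!r}"
                    f"\t{direction}\t{float(du)!r}"
                )
    path.write_text("\n".join(lines) + "\n")


def read_dudl_file(path) -> dict[float, np.ndarray]:
    """TSV of (lambda, dudl) samples -> arrays keyed by coupling value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("lambda", "dudl"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    if df["dudl"].isna().any():
        bad = int(df.index[df["dudl"].isna()][0]) + 2
        raise InputError(f"{path}:{bad}: non-numeric dudl cell")
    return {
        float(lam): grp["dudl"].to_numpy(dtype=float)
        for lam, grp in df.groupby("lambda")
    }


def write_ukn_file(path, rps: ReducedPotentialSet) -> None:
    """Write a u_kn CSV with its YAML comment header."""
    path = Path(path)
    lines = [
        f"# lambdas: {list(map(float, rps.lambdas))}",
        f"# temperature: {float(rps.temperature)}",
        "origin," + ",".join(f"u{k}" for k in range(rps.n_states)),
    ]
    for n in range(rps.n_snapshots):
        row = ",".join(repr(float(v)) for v in rps.u[:, n])
        lines.append(f"{int(rps.origin[n])},{row}")
    path.write_text("\n".join(lines) + "\n")


def read_ukn_file(path) -> ReducedPotentialSet:
    """Read a u_kn CSV; the ``#`` header lines carry lambdas/temperature."""
    path = Path(path)
    meta_lines = []
    body_start = 0
    with path.open() as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            meta_lines.append(line.lstrip("#").strip())
        else:
            body_start = i
            break
    meta = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    if not isinstance(meta, dict) or "lambdas" not in meta or "temperature" not in meta:
        raise InputError(f"{path}: header must declare lambdas and temperature")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])),
                     float_precision="round_trip")
    if "origin" not in df.columns:
        raise InputError(f"{path}: missing origin column")
    u_cols = [c for c in df.columns if c != "origin"]
    return ReducedPotentialSet(
        lambdas=np.asarray(meta["lambdas"], dtype=float),
        u=df[u_cols].to_numpy(dtype=float).T,
        origin=df["origin"].to_numpy(dtype=int),
        temperature=float(meta["temperature"]),
    )


def read_network(edges_path, ligands_path) -> PerturbationNetwork:
    """Assemble a network from edge and ligand CSVs.

    Edge CSV columns: ``from, to, value, se, conformer[, selected]``;
    ligand CSV columns: ``id, set, exp_dg, is_reference[, non_binder]``.
    """
    edf = pd.read_csv(edges_path, dtype={"from": str, "to": str})
    ldf = pd.read_csv(ligands_path, dtype={"id": str})
    for col in ("from", "to", "value", "se"):
        if col not in edf.columns:
            raise InputError(f"{edges_path}: missing column {col!r}")
    for col in ("id", "set", "exp_dg", "is_reference"):
        if col not in ldf.columns:
            raise InputError(f"{ligands_path}: missing column {col!r}")
    ligands = {}
    for _, row in ldf.iterrows():
        exp = row["exp_dg"]
        ligands[row["id"]] = Ligand(
            id=row["id"], set_id=int(row["set"]),
            experimental_dg=None if pd.isna(exp) else float(exp),
            is_reference=bool(row["is_reference"]),
            non_binder=bool(row.get("non_binder", False))
            if "non_binder" in ldf.columns else False,
        )
    edges = []
    for (a, b), grp in edf.groupby(["from", "to"], sort=False):
        cands = tuple(
            EdgeCandidate(
                value=float(r["value"]), se=float(r["se"]),
                conformer=str(r.get("conformer", "conf1")),
            )
            for _, r in grp.iterrows()
        )
        selected = None
        if "selected" in grp.columns and grp["selected"].astype(bool).any():
            pos = int(np.nonzero(grp["selected"].astype(bool).to_numpy())[0][0])
            selected = cands[pos]
        edges.append(PerturbationEdge(str(a), str(b), cands, selected))
    return PerturbationNetwork(ligands=ligands, edges=edges)


_COMPONENT_COLUMNS = (
    "ligand", "bq_ptch", "bq_cosmo", "disp", "bsc", "g_therm", "l_rlx",
    "solv_cosmo", "solv_cosmors",
)


def read_components(path) -> list[EnergyComponents]:
    """Component-table CSV (study column layout) -> EnergyComponents."""
    df = pd.read_csv(path, dtype={"ligand": str})
    missing = [c for c in _COMPONENT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(EnergyComponents(
            ligand=row["ligand"],
            bigqm_ptch=float(row["bq_ptch"]),
            bigqm_cosmo=float(row["bq_cosmo"]),
            dispersion=float(row["disp"]),
            basis_correction=float(row["bsc"]),
            g_therm=float(row["g_therm"]),
            ligand_relax_printed=float(row["l_rlx"]),
            solv_cosmo=float(row["solv_cosmo"]),
            solv_cosmors=float(row["solv_cosmors"]),
        ))
    return out


def read_pairs(path) -> AffinityPairs:
    """Pairs CSV (label, calc[, calc_se], exp[, exp_se]) -> AffinityPairs."""
    df = pd.read_csv(path, dtype={"label": str})
    for col in ("label", "calc", "exp"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    return AffinityPairs(
        labels=df["label"].tolist(),
        calculated=df["calc"].to_numpy(dtype=float),
        experimental=df["exp"].to_numpy(dtype=float),
        calc_se=df["calc_se"].to_numpy(dtype=float)
        if "calc_se" in df.columns else None,
        exp_se=df["exp_se"].to_numpy(dtype=float)
        if "exp_se" in df.columns else None,
    )


def read_frequencies(path, temperature: float | None = None) -> VibrationalModes:
    """Plain-text frequency list (one wavenumber in cm^-1 per line)."""
    path = Path(path)
    values = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values.append(float(line))
        except ValueError:
            raise InputError(f"{path}:{lineno}: non-numeric wavenumber") from None
    if not values:
        raise InputError(f"{path}: no wavenumbers found")
    kwargs = {} if temperature is None else {"temperature": temperature}
    return VibrationalModes(wavenumbers=np.asarray(values), **kwargs)
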