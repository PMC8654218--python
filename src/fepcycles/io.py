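"""Interchange formats: leg TSV, estimate/cycle JSON, pharmacology CSV,
run manifests, and a mapping-driven converter for deposited raw output.

The canonical per-leg format is a purpose-defined TSV: comment lines
(``#`` prefix, key<TAB>value) carry the leg header, the body has the
columns ``replica  window  lambda_i  lambda_j  ensemble  dU`` with
ensemble ∈ {i, j} naming which bracketing λ window the configurations
were sampled at.  Floats are serialized with 17 significant digits so
read∘write is the identity on the data model.  Energies are kcal/mol
everywhere; every JSON document carries an explicit ``units`` field.
"""

from __future__ import annotations

import datetime
import json
from collections import defaultdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fepcycles.cycles import CycleResult
from fepcycles.energetics import FEPLeg, LegEstimate, WindowPair
from fepcycles.errors import ExternalDataError, ParseError
from fepcycles.pharmacology import PharmRecord

FORMAT_VERSION = "1"
_HEADER_KEYS = ("format_version", "temperature_K", "state", "environment",
                "transformation", "schedule_mode")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------
# Leg TSV
# ---------------------------------------------------------------------

def write_leg_tsv(leg: FEPLeg, path) -> None:
    """Write a leg in the canonical TSV dialect."""
    path = Path(path)
    lines = [
        f"# format_version\t{FORMAT_VERSION}",
        f"# temperature_K\t{_fmt(leg.temperature)}",
        f"# state\t{leg.state_label}",
        f"# environment\t{leg.environment}",
        f"# transformation\t{leg.transformation}",
        f"# schedule_mode\t{leg.schedule_mode}",
        "replica\twindow\tlambda_i\tlambda_j\tensemble\tdU",
    ]
    for r, rep in enumerate(leg.windows):
        for w, pair in enumerate(rep):
            li, lj = _fmt(pair.lambda_i), _fmt(pair.lambda_j)
            for ens, arr in (("i", pair.du_from_i), ("j", pair.du_from_j)):
                for du in arr:
                    lines.append(f"{r}\t{w}\t{li}\t{lj}\t{ens}\t{_fmt(du)}")
    path.write_text("\n".join(lines) + "\n")


def read_leg_tsv(path) -> FEPLeg:
    """Read a leg TSV, validating header, schedule and every row.

    Malformed rows raise :class:`ParseError` carrying the 1-based line
    number; no row is ever silently dropped.
    """
    path = Path(path)
    header: dict[str, str] = {}
    # (replica, window) -> {"lambda": (li, lj), "i": [...], "j": [...]}
    acc: dict[tuple[int, int], dict] = defaultdict(
        lambda: {"lambda": None, "i": [], "j": []})
    saw_column_row = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    header[parts[0].strip()] = parts[1].strip()
                continue
            if not saw_column_row:
                saw_column_row = True
                if line.split("\t")[0] == "replica":
                    continue            # column header row
            fields = line.split("\t")
            if len(fields) != 6:
                raise ParseError(f"expected 6 tab-separated fields, "
                                 f"got {len(fields)}", line=lineno)
            try:
                r, w = int(fields[0]), int(fields[1])
                li, lj = float(fields[2]), float(fields[3])
                du = float(fields[5])
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
            ens = fields[4]
            if ens not in ("i", "j"):
                raise ParseError(f"unknown ensemble token {ens!r}",
                                 line=lineno)
            if not np.isfinite(du):
                raise ParseError(f"non-finite dU {fields[5]!r}", line=lineno)
            slot = acc[(r, w)]
            if slot["lambda"] is None:
                slot["lambda"] = (li, lj)
            elif slot["lambda"] != (li, lj):
                raise ParseError(
                    f"inconsistent λ pair for replica {r} window {w}",
                    line=lineno)
            slot[ens].append(du)

    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ParseError(f"missing header key(s): {', '.join(missing)}")
    if header["format_version"] != FORMAT_VERSION:
        raise ParseError(
            f"unrecognized format_version {header['format_version']!r}")
    if not acc:
        raise ParseError("file contains no sample rows")

    replicas = sorted({r for r, _ in acc})
    if replicas != list(range(len(replicas))):
        raise ParseError(f"replica indices not contiguous: {replicas}")
    ref_windows = sorted(w for r, w in acc if r == replicas[0])
    windows = []
    for r in replicas:
        wins = sorted(w for rr, w in acc if rr == r)
        if wins != ref_windows:
            raise ParseError(f"replica {r} window set differs from replica 0")
        pairs = []
        for w in wins:
            slot = acc[(r, w)]
            if not slot["i"] or not slot["j"]:
                raise ParseError(
                    f"replica {r} window {w} lacks samples from one ensemble")
            li, lj = slot["lambda"]
            pairs.append(WindowPair(lambda_i=li, lambda_j=lj,
                                    du_from_i=np.array(slot["i"]),
                                    du_from_j=np.array(slot["j"])))
        pairs.sort(key=lambda p: p.lambda_i)
        windows.append(pairs)
    return FEPLeg(windows=windows,
                  temperature=float(header["temperature_K"]),
                  state_label=header["state"],
                  environment=header["environment"],
                  transformation=header["transformation"],
                  schedule_mode=header["schedule_mode"])


# ---------------------------------------------------------------------
# Estimate / cycle JSON
# ---------------------------------------------------------------------

def _estimate_dict(est: LegEstimate) -> dict:
    return {
        "units": "kcal/mol",
        "per_replica_dg": list(est.per_replica_dg),
        "mean_dg": est.mean_dg,
        "sem_dg": est.sem_dg,
        "n_replicas": est.n_replicas,
        "state": est.state_label,
        "environment": est.environment,
        "transformation": est.transformation,
        "temperature_K": est.temperature,
    }


def write_estimate_json(est: LegEstimate, path) -> None:
    doc = {"format": "fepcycles-estimate", **_estimate_dict(est)}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _estimate_from_dict(d: dict) -> LegEstimate:
    try:
        return LegEstimate(
            per_replica_dg=tuple(float(v) for v in d["per_replica_dg"]),
            mean_dg=float(d["mean_dg"]),
            sem_dg=None if d["sem_dg"] is None else float(d["sem_dg"]),
            n_replicas=int(d["n_replicas"]),
            state_label=d["state"], environment=d["environment"],
            transformation=d["transformation"],
            temperature=float(d["temperature_K"]))
    except KeyError as exc:
        raise ParseError(f"estimate JSON missing key {exc}") from None


def read_estimate_json(path) -> LegEstimate:
    return _estimate_from_dict(json.loads(Path(path).read_text()))


def write_cycle_json(result: CycleResult, path) -> None:
    doc = {
        "format": "fepcycles-cycle",
        "units": "kcal/mol",
        "kind": result.kind,
        "ddg": result.ddg,
        "sem": result.sem,
        "components": {role: _estimate_dict(leg)
                       for role, leg in result.components.items()},
        "decomposition": (
            None if result.decomposition is None else
            {name: {"value": v, "sem": s, "units": "kcal/mol"}
             for name, (v, s) in result.decomposition.items()}),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_cycle_json(path) -> CycleResult:
    d = json.loads(Path(path).read_text())
    decomp = None
    if d.get("decomposition") is not None:
        decomp = {name: (t["value"], t["sem"])
                  for name, t in d["decomposition"].items()}
    return CycleResult(
        kind=d["kind"], ddg=float(d["ddg"]),
        sem=None if d["sem"] is None else float(d["sem"]),
        components={role: _estimate_from_dict(e)
                    for role, e in d.get("components", {}).items()},
        decomposition=decomp)


def format_cycle_report(results: list[tuple[str, CycleResult]]) -> str:
    """Human-readable table: label, kind, ΔΔG ± SEM, qualitative call."""
    rows = [("label", "kind", "ddG (kcal/mol)", "SEM", "call")]
    for label, res in results:
        rows.append((label, res.kind, f"{res.ddg:+.3f}",
                     "n/a" if res.sem is None else f"{res.sem:.3f}",
                     res.qualitative_call()))
    widths = [max(len(r[c]) for r in rows) for c in range(5)]
    lines = ["  ".join(r[c].ljust(widths[c]) for c in range(5))
             for r in rows]
    lines.insert(1, "  ".join("-" * w for w in widths))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------
# Pharmacology CSV
# ---------------------------------------------------------------------

def read_pharm_csv(path) -> list[PharmRecord]:
    """Read pharmacology records.

    Columns: ligand, variant, emax_percent, emax_sem, and optionally
    ec50_nM and profile.
    """
    df = pd.read_csv(path)
    needed = {"ligand", "variant", "emax_percent", "emax_sem"}
    missing = needed - set(df.columns)
    if missing:
        raise ParseError(f"pharmacology CSV missing column(s): "
                         f"{', '.join(sorted(missing))}")
    records = []
    for _, row in df.iterrows():
        ec50 = None
        if "ec50_nM" in df.columns and pd.notna(row["ec50_nM"]):
            ec50 = float(row["ec50_nM"])
        profile = None
        if "profile" in df.columns and pd.notna(row["profile"]):
            profile = str(row["profile"])
        records.append(PharmRecord(
            ligand=str(row["ligand"]),
            receptor_variant=str(row["variant"]),
            emax_percent=float(row["emax_percent"]),
            emax_sem=float(row["emax_sem"]),
            ec50=ec50, profile=profile))
    return records


def write_pharm_csv(records: list[PharmRecord], path) -> None:
    df = pd.DataFrame([{
        "ligand": r.ligand, "variant": r.receptor_variant,
        "emax_percent": r.emax_percent, "emax_sem": r.emax_sem,
        "ec50_nM": r.ec50, "profile": r.profile,
    } for r in records])
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------

def write_manifest(path, command: str, seed: int | None,
                   inputs: dict, outputs: list) -> None:
    """Record what a pipeline command did: inputs, seed, version, time."""
    from fepcycles import __version__
    doc = {
        "command": command,
        "seed": seed,
        "inputs": inputs,
        "outputs": [str(o) for o in outputs],
        "fepcycles_version": __version__,
        "timestamp": datetime.datetime.now(
            datetime.timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ---------------------------------------------------------------------
# Converter for deposited raw energy outputs
# ---------------------------------------------------------------------

def convert_deposited_energies(input_dir, mapping_config,
                               output_dir=None) -> list[Path]:
    """Best-effort conversion of deposited per-window energy records.

    The published raw FEP output must be downloaded separately; its
    internal layout is not standardized, so a mapping config names
    which file belongs to which leg/replica/window.  Mapping schema
    (YAML or dict)::

        legs:
          - output: <name>.tsv
            temperature_K: 298.0
            state: R | Rstar
            environment: apo | bound
            transformation: <label>
            schedule_mode: <text>
            files:
              - path: <relative path>      # plain-text numeric table
                replica: <int>
                window: <int>
                lambda_i: <float>
                lambda_j: <float>
                ensemble: i | j
                column: <int, default 0>   # column holding dU (kcal/mol)

    Returns the list of written leg-TSV paths; an empty mapping yields
    an empty list.  Every converted file is logged in a provenance
    sidecar next to each output TSV.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ExternalDataError(
            f"external data required: deposit directory {input_dir} not "
            "found; download the study's raw output archive and unpack it "
            "there")
    if not isinstance(mapping_config, dict):
        mapping_config = yaml.safe_load(Path(mapping_config).read_text())
    legs = (mapping_config or {}).get("legs", [])
    if output_dir is None:
        output_dir = input_dir / "converted"
    output_dir = Path(output_dir)
    written: list[Path] = []
    for leg_cfg in legs:
        acc: dict[tuple[int, int], dict] = defaultdict(
            lambda: {"lambda": None, "i": [], "j": []})
        provenance = []
        for fc in leg_cfg["files"]:
            fpath = input_dir / fc["path"]
            col = int(fc.get("column", 0))
            values = []
            try:
                with fpath.open() as fh:
                    for lineno, raw in enumerate(fh, start=1):
                        line = raw.strip()
                        if not line or line.startswith("#"):
                            continue
                        parts = line.split()
                        try:
                            values.append(float(parts[col]))
                        except (IndexError, ValueError):
                            raise ParseError(
                                f"{fpath}: unparseable record {line!r}",
                                line=lineno) from None
            except FileNotFoundError:
                raise ExternalDataError(
                    f"external data required: {fpath} listed in the "
                    "mapping config is missing from the deposit") from None
            key = (int(fc["replica"]), int(fc["window"]))
            slot = acc[key]
            lam = (float(fc["lambda_i"]), float(fc["lambda_j"]))
            if slot["lambda"] is None:
                slot["lambda"] = lam
            elif slot["lambda"] != lam:
                raise ParseError(
                    f"conflicting λ pair for replica/window {key} "
                    f"in mapping for {leg_cfg['output']}")
            slot[fc["ensemble"]].extend(values)
            provenance.append({"source": str(fpath), "rows": len(values),
                               "replica": key[0], "window": key[1],
                               "ensemble": fc["ensemble"]})
        replicas = sorted({r for r, _ in acc})
        windows = []
        for r in replicas:
            pairs = []
            for w in sorted(w for rr, w in acc if rr == r):
                slot = acc[(r, w)]
                li, lj = slot["lambda"]
                pairs.append(WindowPair(lambda_i=li, lambda_j=lj,
                                        du_from_i=np.array(slot["i"]),
                                        du_from_j=np.array(slot["j"])))
            windows.append(pairs)
        leg = FEPLeg(windows=windows,
                     temperature=float(leg_cfg.get("temperature_K", 298.0)),
                     state_label=leg_cfg["state"],
                     environment=leg_cfg["environment"],
                     transformation=leg_cfg["transformation"],
                     schedule_mode=leg_cfg.get("schedule_mode", "unknown"))
        output_dir.mkdir(parents=True, exist_ok=True)
        out_path = output_dir / leg_cfg["output"]
        write_leg_tsv(leg, out_path)
        out_path.with_suffix(out_path.suffix + ".provenance.json").write_text(
            json.dumps(provenance, indent=2) + "\n")
        written.append(out_path)
    return written
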