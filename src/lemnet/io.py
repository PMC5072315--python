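"""File formats: expression tables, edge lists, priors, network specs.

The canonical on-disk dialect is tab-separated text with ``#`` comment
lines. Every artifact written by the package starts with a comment header
recording the tool version, the seed, and a hash of the configuration
that produced it, so a run can be reproduced from its outputs alone.

Expression tables: a header row ``gene`` followed by the numeric time
labels, then one row per gene. Gold standards and extracted networks:
three columns (target, regulator, sign). Posterior tables: one scored
candidate edge per row with its probability, loss, and fitted parameters
in data units. Network specifications: YAML (or JSON, a YAML subset).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model_core import (
    EdgeModel,
    ExpressionDataset,
    Gate,
    NetworkSpec,
    NodeRule,
    Sign,
)
from .infer import EdgeScore, InferenceResult, NodePosterior, PriorSpec

__all__ = [
    "FormatError",
    "artifact_header",
    "config_hash",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_priors",
    "write_priors",
    "write_posteriors",
    "read_posteriors",
    "read_network_spec",
    "write_network_spec",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect; the message names
    the offending row/column."""


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def artifact_header(seed: "int | None" = None, config: "dict | None" = None) -> str:
    """Comment header stamped on every written artifact."""
    parts = [f"lemnet {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return "# " + "; ".join(parts) + "\n"


def _read_lines(path: "str | Path") -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    text = Path(path).read_text()
    out = []
    for i, line in enumerate(text.splitlines(), start=1):
        if line.strip() and not line.lstrip().startswith("#"):
            out.append((i, line))
    return out


def read_expression(path: "str | Path") -> ExpressionDataset:
    """Read a tab-separated expression table.

    Validates the header (``gene`` + strictly increasing numeric time
    labels), rectangularity, numeric cells, and gene-name uniqueness;
    errors name the offending row and column. Decimal separator is always
    the dot, independent of locale.
    """
    path = Path(path)
    lines = _read_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty expression table")
    hdr_no, hdr = lines[0]
    cols = hdr.split("\t")
    if cols[0].strip().lower() != "gene":
        raise FormatError(
            f"{path}:{hdr_no}: header must start with 'gene', got {cols[0]!r}"
        )
    if len(cols) < 4:
        raise FormatError(f"{path}:{hdr_no}: need at least 3 time columns")
    times = []
    for j, label in enumerate(cols[1:], start=2):
        try:
            times.append(float(label))
        except ValueError:
            raise FormatError(
                f"{path}:{hdr_no}: time label in column {j} is not numeric: {label!r}"
            ) from None
    for j in range(1, len(times)):
        if times[j] <= times[j - 1]:
            raise FormatError(
                f"{path}:{hdr_no}: time labels must be strictly increasing "
                f"(column {j + 2}: {times[j]} after {times[j - 1]})"
            )
    names: list[str] = []
    rows: list[list[float]] = []
    for line_no, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise FormatError(
                f"{path}:{line_no}: expected {len(cols)} columns, got {len(cells)}"
            )
        name = cells[0].strip()
        if name in names:
            raise FormatError(f"{path}:{line_no}: duplicate gene name {name!r}")
        vals = []
        for j, cell in enumerate(cells[1:], start=2):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{line_no}: non-numeric cell in column {j}: {cell!r}"
                ) from None
        names.append(name)
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no gene rows")
    try:
        return ExpressionDataset(names, np.array(times), np.array(rows))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(
    data: ExpressionDataset,
    path: "str | Path",
    seed: "int | None" = None,
    config: "dict | None" = None,
) -> None:
    buf = _io.StringIO()
    buf.write(artifact_header(seed=seed, config=config))
    buf.write("gene\t" + "\t".join(repr(float(t)) for t in data.times) + "\n")
    for name, row in zip(data.gene_names, data.values):
        buf.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_edge_list(path: "str | Path") -> list[EdgeModel]:
    """Read a signed edge list: columns target, regulator, sign (a|r).
    A header row is optional and detected by its column names."""
    path = Path(path)
    lines = _read_lines(path)
    edges = []
    for line_no, line in lines:
        cells = [c.strip() for c in line.split("\t")]
        if line_no == lines[0][0] and cells[:2] == ["target", "regulator"]:
            continue
        if len(cells) < 3:
            raise FormatError(
                f"{path}:{line_no}: need 3 columns (target, regulator, sign)"
            )
        try:
            sign = Sign.parse(cells[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{line_no}: {exc}") from None
        edges.append(EdgeModel(cells[0], cells[1], sign))
    return edges


def write_edge_list(
    edges: list[EdgeModel],
    path: "str | Path",
    seed: "int | None" = None,
    config: "dict | None" = None,
) -> None:
    buf = _io.StringIO()
    buf.write(artifact_header(seed=seed, config=config))
    buf.write("target\tregulator\tsign\n")
    for e in edges:
        buf.write(f"{e.target}\t{e.regulator}\t{e.sign.value}\n")
    Path(path).write_text(buf.getvalue())


def read_priors(path: "str | Path") -> PriorSpec:
    """Read a two-column (gene, role) table; roles are activator,
    repressor, or both."""
    path = Path(path)
    roles = {}
    for line_no, line in _read_lines(path):
        cells = [c.strip() for c in line.split("\t")]
        if cells[:2] == ["gene", "role"]:
            continue
        if len(cells) < 2:
            raise FormatError(f"{path}:{line_no}: need 2 columns (gene, role)")
        if cells[1] not in ("activator", "repressor", "both"):
            raise FormatError(
                f"{path}:{line_no}: role must be activator/repressor/both, "
                f"got {cells[1]!r}"
            )
        roles[cells[0]] = cells[1]
    return PriorSpec(roles)


def write_priors(prior: PriorSpec, path: "str | Path") -> None:
    buf = _io.StringIO()
    buf.write(artifact_header())
    buf.write("gene\trole\n")
    for gene in sorted(prior.roles):
        buf.write(f"{gene}\t{prior.roles[gene]}\n")
    Path(path).write_text(buf.getvalue())


_POSTERIOR_COLUMNS = [
    "target", "regulator", "sign", "probability", "loss_star",
    "alpha", "beta", "gamma", "n", "K",
]


def write_posteriors(
    result: InferenceResult,
    path: "str | Path",
    seed: "int | None" = None,
    config: "dict | None" = None,
) -> None:
    """Write every scored candidate edge with its posterior probability and
    fitted parameters mapped back to data units."""
    rows = []
    for post in result.posteriors:
        for score in post.scores:
            th = result.theta_in_data_units(score)
            rows.append(
                {
                    "target": score.edge.target,
                    "regulator": score.edge.regulator,
                    "sign": score.edge.sign.value,
                    "probability": post.probabilities[score.edge],
                    "loss_star": score.loss_star,
                    "alpha": th.alpha,
                    "beta": th.beta,
                    "gamma": th.gamma,
                    "n": th.n,
                    "K": th.K,
                }
            )
    df = pd.DataFrame(rows, columns=_POSTERIOR_COLUMNS)
    with open(path, "w") as fh:
        fh.write(artifact_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_posteriors(path: "str | Path") -> pd.DataFrame:
    """Read a posterior table back as a DataFrame (columns as written)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _POSTERIOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: posterior table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Network specifications (YAML / JSON)
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: NetworkSpec) -> dict:
    nodes = {}
    for g in spec.nodes:
        rule = spec.rules[g]
        nodes[g] = {
            "inputs": [
                {"regulator": reg, "sign": sign.value, "n": n, "K": K}
                for (reg, sign), (n, K) in zip(rule.inputs, rule.hill_params)
            ],
            "alpha": rule.alpha,
            "beta": rule.beta,
            "gamma": rule.gamma,
        }
        if rule.gate is not None:
            nodes[g]["gate"] = rule.gate.value
    return {
        "nodes": list(spec.nodes),
        "rules": nodes,
        "initial_state": dict(spec.initial_state),
    }


def write_network_spec(spec: NetworkSpec, path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write(artifact_header())
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def read_network_spec(path: "str | Path") -> NetworkSpec:
    """Read a network specification from YAML (JSON is a YAML subset)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "nodes" not in raw or "rules" not in raw:
        raise FormatError(f"{path}: spec must define 'nodes' and 'rules'")
    rules = {}
    for g, r in raw["rules"].items():
        inputs = [(i["regulator"], Sign.parse(i["sign"])) for i in r.get("inputs", [])]
        hill_params = [(float(i["n"]), float(i["K"])) for i in r.get("inputs", [])]
        gate = Gate(r["gate"]) if "gate" in r else None
        rules[g] = NodeRule(
            inputs=inputs,
            gate=gate,
            hill_params=hill_params,
            alpha=float(r.get("alpha", 1.0)),
            beta=float(r.get("beta", 1.0)),
            gamma=float(r.get("gamma", 0.0)),
        )
    try:
        return NetworkSpec(
            list(raw["nodes"]),
            rules,
            initial_state={k: float(v) for k, v in raw.get("initial_state", {}).items()},
        )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
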