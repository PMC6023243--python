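"""Model-file parsing and tabular report writers.

Models are stored as human-writable JSON: a ``states`` list with contiguous
1-based ids, labels and per-state measurement values, an ``edges`` list of
``{"from", "to", "rate"}`` records (edge order = file order), and
``n_walkers``.  Floats are serialized with ``repr`` (17 significant digits),
so write-then-parse round-trips bit-identically.  Tabular outputs are TSV
with a commented metadata header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

from .network import MarkovNetworkModel, ModelValidationError, build_model

__all__ = ["parse_model_file", "write_model_file", "model_to_dict", "write_tsv"]


def model_to_dict(model: MarkovNetworkModel) -> dict:
    """JSON-ready dict in the canonical key order."""
    return {
        "states": [
            {"id": i + 1, "label": model.state_labels[i],
             "measurement": float(model.measurement[i])}
            for i in range(model.n_states)
        ],
        "edges": [
            {"from": e.source, "to": e.target, "rate": float(e.rate)}
            for e in model.edges
        ],
        "n_walkers": model.n_walkers,
    }


def write_model_file(model: MarkovNetworkModel, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1) + "\n")


def parse_model_file(path) -> MarkovNetworkModel:
    """Load and validate a model JSON file.

    Raises :class:`ModelValidationError` naming the offending field for
    schema violations, non-contiguous state ids, duplicate edges, or a
    missing measurement.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelValidationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelValidationError(f"{path}: top level must be a JSON object")
    for key in ("states", "edges"):
        if key not in doc:
            raise ModelValidationError(f"{path}: missing required field {key!r}")

    states = []
    measurement = []
    for pos, rec in enumerate(doc["states"], start=1):
        if not isinstance(rec, dict) or "id" not in rec:
            raise ModelValidationError(f"{path}: states[{pos - 1}] must be an object with 'id'")
        if rec["id"] != pos:
            raise ModelValidationError(
                f"{path}: state ids must be contiguous 1..n in order; "
                f"got id {rec['id']} at position {pos}"
            )
        if "measurement" not in rec:
            raise ModelValidationError(
                f"{path}: state {pos} lacks the required 'measurement' field"
            )
        states.append((pos, rec.get("label", str(pos))))
        measurement.append(float(rec["measurement"]))

    edges = []
    for pos, rec in enumerate(doc["edges"], start=1):
        for key in ("from", "to", "rate"):
            if key not in rec:
                raise ModelValidationError(
                    f"{path}: edges[{pos - 1}] lacks required field {key!r}"
                )
        edges.append((int(rec["from"]), int(rec["to"]), float(rec["rate"])))

    n_walkers = doc.get("n_walkers", 1)
    return build_model(states, edges, measurement, n_walkers=n_walkers)


def write_tsv(path, columns: dict, metadata: Iterable[str] = ()) -> None:
    """Write named columns as TSV with '#'-prefixed metadata header lines."""
    names = list(columns)
    n_rows = len(next(iter(columns.values())))
    with open(path, "w") as fh:
        for line in metadata:
            fh.write(f"# {line}\n")
        fh.write("\t".join(names) + "\n")
        for i in range(n_rows):
            fh.write("\t".join(_fmt(columns[c][i]) for c in names) + "\n")


def _fmt(x) -> str:
    # float() first: NumPy scalars subclass float but repr as np.float64(...)
    if isinstance(x, float):
        return repr(float(x))
    return str(x)
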