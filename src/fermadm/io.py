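"""Reading and writing decision tensors and ranking reports.

Canonical interchange is a versioned JSON document::

    {
      "schema_version": 1,
      "alternatives": ["A1", ...],          # m labels
      "attributes":   ["C1", ...],          # n labels
      "periods":      ["t1", ...],          # p labels
      "time_weights":      [...],           # p weights, sum 1
      "attribute_weights": [...],           # n weights, sum 1
      "matrices": [ [[ [mu, nu], ... ]] ]   # p matrices of m x n pairs
    }

A CSV dialect is also supported: a directory holding one ``period_XX.csv``
per time period (header row of attribute labels, one row per alternative,
cells written ``"mu;nu"``) plus a ``weights.csv`` sidecar with ``time`` and
``attribute`` rows. JSON carries floats at full precision, so a round trip
reproduces a tensor bit-exactly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

from .core import FFNValidationError
from .pipeline import RankingReport, TemporalDecisionTensor
from .weights import WeightVector

__all__ = [
    "SCHEMA_VERSION",
    "TensorDocumentError",
    "load_tensor",
    "write_tensor",
    "write_report",
]

SCHEMA_VERSION = 1


class TensorDocumentError(ValueError):
    """A tensor document is malformed; the message names the offending part."""


def _require(doc: dict, key: str):
    if key not in doc:
        raise TensorDocumentError(f"missing required field {key!r}")
    return doc[key]


def _parse_document(doc: dict, mode: str) -> tuple[TemporalDecisionTensor, WeightVector, WeightVector]:
    version = _require(doc, "schema_version")
    if version != SCHEMA_VERSION:
        raise TensorDocumentError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    alternatives = list(_require(doc, "alternatives"))
    attributes = list(_require(doc, "attributes"))
    periods = list(_require(doc, "periods"))
    matrices = _require(doc, "matrices")
    if len(matrices) != len(periods):
        raise TensorDocumentError(
            f"{len(matrices)} matrices for {len(periods)} period labels"
        )
    for k, matrix in enumerate(matrices):
        if len(matrix) != len(alternatives):
            raise TensorDocumentError(
                f"matrix {periods[k]!r}: {len(matrix)} rows for "
                f"{len(alternatives)} alternatives"
            )
        for i, row in enumerate(matrix):
            if len(row) != len(attributes):
                raise TensorDocumentError(
                    f"matrix {periods[k]!r}, row {alternatives[i]!r}: "
                    f"{len(row)} cells for {len(attributes)} attributes"
                )
            for j, cell in enumerate(row):
                if not (isinstance(cell, (list, tuple)) and len(cell) == 2):
                    raise TensorDocumentError(
                        f"matrix {periods[k]!r}, cell ({alternatives[i]!r}, "
                        f"{attributes[j]!r}): expected [mu, nu], got {cell!r}"
                    )
    try:
        eps = WeightVector.of(_require(doc, "time_weights"), "time")
        omega = WeightVector.of(_require(doc, "attribute_weights"), "attribute")
    except ValueError as exc:
        raise TensorDocumentError(str(exc)) from exc
    if len(eps) != len(periods):
        raise TensorDocumentError(
            f"{len(eps)} time weights for {len(periods)} periods"
        )
    if len(omega) != len(attributes):
        raise TensorDocumentError(
            f"{len(omega)} attribute weights for {len(attributes)} attributes"
        )
    try:
        tensor = TemporalDecisionTensor.from_period_matrices(
            matrices, alternatives, attributes, periods, mode=mode
        )
    except FFNValidationError as exc:
        raise TensorDocumentError(str(exc)) from exc
    return tensor, eps, omega


def load_tensor(
    path: str | Path, format: str | None = None, mode: str = "strict"
) -> tuple[TemporalDecisionTensor, WeightVector, WeightVector]:
    """Load ``(tensor, time_weights, attribute_weights)`` from JSON or CSV.

    ``format`` is inferred from the path when omitted: a directory means the
    CSV dialect, anything else JSON.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.is_dir() else "json"
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise TensorDocumentError(f"{path}: not valid JSON ({exc})") from exc
        return _parse_document(doc, mode)
    if format == "csv":
        return _load_csv_dir(path, mode)
    raise ValueError(f"format must be 'json' or 'csv', got {format!r}")


def _load_csv_dir(path: Path, mode: str):
    weights_file = path / "weights.csv"
    if not weights_file.exists():
        raise TensorDocumentError(f"missing weights sidecar {weights_file}")
    weight_rows = {}
    with weights_file.open(newline="") as fh:
        for row in csv.reader(fh):
            if row:
                weight_rows[row[0].strip()] = [float(x) for x in row[1:]]
    for kind in ("time", "attribute"):
        if kind not in weight_rows:
            raise TensorDocumentError(f"weights.csv is missing the {kind!r} row")
    period_files = sorted(path.glob("period_*.csv"))
    if not period_files:
        raise TensorDocumentError(f"no period_*.csv files in {path}")
    matrices = []
    alternatives: list[str] | None = None
    attributes: list[str] | None = None
    for pf in period_files:
        with pf.open(newline="") as fh:
            rows = list(csv.reader(fh))
        header, body = rows[0], rows[1:]
        attrs = [h.strip() for h in header[1:]]
        alts = [r[0].strip() for r in body]
        if attributes is None:
            attributes, alternatives = attrs, alts
        elif attrs != attributes or alts != alternatives:
            raise TensorDocumentError(f"{pf.name}: labels differ from other periods")
        matrix = []
        for r in body:
            parsed = []
            for cell in r[1:]:
                try:
                    mu, nu = cell.split(";")
                    parsed.append((float(mu), float(nu)))
                except ValueError as exc:
                    raise TensorDocumentError(
                        f"{pf.name}: cannot parse cell {cell!r} as 'mu;nu'"
                    ) from exc
            matrix.append(parsed)
        matrices.append(matrix)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "alternatives": alternatives,
        "attributes": attributes,
        "periods": [pf.stem.replace("period_", "t") for pf in period_files],
        "time_weights": weight_rows["time"],
        "attribute_weights": weight_rows["attribute"],
        "matrices": matrices,
    }
    return _parse_document(doc, mode)


def write_tensor(
    tensor: TemporalDecisionTensor,
    eps: WeightVector,
    omega: WeightVector,
    path: str | Path,
    format: str = "json",
) -> Path:
    """Serialize a tensor plus its weight vectors; inverse of :func:`load_tensor`."""
    path = Path(path)
    m, n, p = tensor.shape
    if format == "json":
        doc = {
            "schema_version": SCHEMA_VERSION,
            "alternatives": list(tensor.alternatives),
            "attributes": list(tensor.attributes),
            "periods": list(tensor.periods),
            "time_weights": list(eps.weights),
            "attribute_weights": list(omega.weights),
            "matrices": [
                [
                    [[tensor.cells[i][j][k].mu, tensor.cells[i][j][k].nu] for j in range(n)]
                    for i in range(m)
                ]
                for k in range(p)
            ],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
        return path
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with (path / "weights.csv").open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", *[repr(x) for x in eps.weights]])
            w.writerow(["attribute", *[repr(x) for x in omega.weights]])
        for k in range(p):
            with (path / f"period_{k + 1:02d}.csv").open("w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["alternative", *tensor.attributes])
                for i in range(m):
                    w.writerow(
                        [tensor.alternatives[i]]
                        + [
                            f"{tensor.cells[i][j][k].mu!r};{tensor.cells[i][j][k].nu!r}"
                            for j in range(n)
                        ]
                    )
        return path
    raise ValueError(f"format must be 'json' or 'csv', got {format!r}")


def write_report(report: RankingReport, path: str | Path, format: str = "json") -> Path:
    """Write a ranking report as JSON (full precision), TSV, or plain text.

    The text format rounds to 3 decimals and prints the ranking with ``≻``
    separators; machine formats keep full precision.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=1) + "\n")
    elif format == "tsv":
        lines = ["alternative\tmu\tnu\tscore\taccuracy"]
        for label, f, s, h in zip(
            report.alternatives, report.overall, report.scores, report.accuracies
        ):
            lines.append(f"{label}\t{f.mu!r}\t{f.nu!r}\t{s!r}\t{h!r}")
        lines.append("# ranking: " + " > ".join(",".join(g) for g in report.ranking))
        path.write_text("\n".join(lines) + "\n")
    elif format == "text":
        path.write_text(format_report(report))
    else:
        raise ValueError(f"format must be 'json', 'tsv' or 'text', got {format!r}")
    return path


def format_report(report: RankingReport) -> str:
    """Render a report the way results tables are conventionally printed."""
    lines = [f"variant: {report.variant}"]
    if report.violations:
        lines.append(f"constraint violations tolerated: {len(report.violations)}")
    lines.append("alternative  overall (mu, nu)   score    accuracy")
    for label, f, s, h in zip(
        report.alternatives, report.overall, report.scores, report.accuracies
    ):
        lines.append(
            f"{label:<12} ({f.mu:.3f}, {f.nu:.3f})     {s: .3f}   {h:.3f}"
        )
    lines.append("ranking: " + report.ranking_string())
    return "\n".join(lines) + "\n"
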