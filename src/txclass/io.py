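"""TSV/CSV/JSON format adapters.

TSV is the canonical interchange (gene x sample matrices with a header row
of sample ids and a first column of gene ids, matching typical expression
dumps); CSV is accepted on read by sniffing the delimiter. Round-tripping a
count matrix through write/read is lossless for integer counts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from txclass.containers import CountMatrix, DataError, ExpressionMatrix, TransformStats
from txclass.deg import FeaturePanel
from txclass.sim import TruthTable


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_counts(counts_path: str | Path, labels_path: str | Path) -> CountMatrix:
    counts = _read_table(counts_path)
    labels = read_labels(labels_path)
    return CountMatrix(counts, labels)


def write_counts(cm: CountMatrix, counts_path: str | Path, labels_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    write_labels(cm.labels, labels_path)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="," if str(path).endswith(".csv") else "\t")
    if df.shape[1] < 2:
        raise DataError("labels file needs two columns: sample_id, class")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="class")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "class": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_panel(path: str | Path) -> FeaturePanel:
    genes = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return FeaturePanel(genes)


def write_panel(panel: FeaturePanel, path: str | Path) -> None:
    Path(path).write_text("\n".join(panel.genes) + "\n")


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "log2FC", "wald_stat", "pvalue", "padj"]
    table[cols].rename(columns={"wald_stat": "stat"}).to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthTable, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthTable:
    return TruthTable(pd.read_csv(path, sep="\t"))


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    em.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = _read_table(path)
    labels = df.pop("class").to_numpy()
    provenance = df.pop("provenance").to_numpy()
    return ExpressionMatrix(
        df.to_numpy(dtype=np.float64),
        [str(s) for s in df.index],
        [str(c) for c in df.columns],
        labels,
        provenance,
    )


def write_transform_stats(stats: TransformStats, path: str | Path) -> None:
    payload = {
        "features": stats.features,
        "mean": stats.mean.tolist(),
        "sd": stats.sd.tolist(),
        "log_geomeans": {
            g: (float(v) if np.isfinite(v) else None)
            for g, v in stats.log_geomeans.items()
        },
        "sf_log_scale": stats.sf_log_scale,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_transform_stats(path: str | Path) -> TransformStats:
    payload = json.loads(Path(path).read_text())
    lg = pd.Series(
        {g: (-np.inf if v is None else v) for g, v in payload["log_geomeans"].items()}
    )
    return TransformStats(
        features=payload["features"],
        mean=np.asarray(payload["mean"]),
        sd=np.asarray(payload["sd"]),
        log_geomeans=lg,
        sf_log_scale=float(payload.get("sf_log_scale", 0.0)),
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
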