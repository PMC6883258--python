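"""Delimited-text readers/writers and the run report.

All tabular inputs are CSV/TSV with a header row and a sample-ID first
column.  Missing values are a hard error (analyses assume complete data;
eliminate or impute upstream), as are duplicated sample IDs.  Files are
aligned on the intersection of their sample IDs, with the number of dropped
samples logged.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "align_samples",
    "write_results",
    "read_results",
    "beta_to_mvalue",
    "mvalue_to_beta",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_matrix(path, orientation: str = "samples_rows") -> pd.DataFrame:
    """Read a labeled numeric matrix; strict about missing cells and IDs."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "features_rows":
        df = df.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated sample IDs {dups[:5]}")
    na = df.isna()
    if na.to_numpy().any():
        r, c = np.argwhere(na.to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at sample {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric columns {non_numeric[:5]}")
    return df


def align_samples(*frames: pd.DataFrame) -> list[pd.DataFrame]:
    """Inner-join frames on sample ID; logs how many samples were dropped."""
    common = frames[0].index
    for f in frames[1:]:
        common = common.intersection(f.index)
    if len(common) == 0:
        raise ValueError("no common sample IDs across input files")
    dropped = max(len(f) for f in frames) - len(common)
    if dropped:
        logger.info("dropped %d samples absent from some inputs", dropped)
    return [f.loc[common] for f in frames]


def beta_to_mvalue(beta):
    """Logit transform of methylation proportions: M = log(beta/(1-beta))."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta values must lie strictly in (0, 1)")
    return np.log(beta / (1.0 - beta))


def mvalue_to_beta(m):
    """Inverse of :func:`beta_to_mvalue`."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp(-m))


def write_results(result, prefix, mediator_names=None, extra_report=None):
    """Write the per-mediator TSV and a JSON run report; returns both paths.

    ``result`` is a MediationResult; the TSV has the RESULT_COLUMNS schema
    (with mediator_id replaced by names when given).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table = result.table.copy()
    if mediator_names is not None:
        table["mediator_id"] = np.asarray(mediator_names)[
            table["mediator_id"].to_numpy()
        ]
    table["method"] = result.method
    tsv_path = prefix.with_suffix(".results.tsv")
    table.to_csv(tsv_path, sep="\t", index=False)

    from . import __version__

    report = {
        "tool_version": __version__,
        "method": result.method,
        "c_hat": result.c_hat,
        "c_hat_se": result.c_hat_se,
        "c_hat_p": result.c_hat_p,
        "c_prime_hat": result.c_prime_hat,
        "alpha": result.alpha,
        "d": result.d,
        "n_significant": int(len(result.significant)),
        "S_size": int(len(result.S)),
        # bulky per-mediator arrays go to the diagnostics TSVs, not the report
        "details": {
            key: (val.tolist() if isinstance(val, np.ndarray) else val)
            for key, val in result.details.items()
            if key not in ("screen_scores", "screen_ranked", "b_lasso")
        },
    }
    if extra_report:
        report.update(extra_report)
    json_path = prefix.with_suffix(".report.json")
    json_path.write_text(json.dumps(report, indent=2, default=float))
    return tsv_path, json_path


def read_results(tsv_path) -> pd.DataFrame:
    """Round-trip reader for the results TSV."""
    return pd.read_csv(tsv_path, sep="\t")


def write_diagnostics(result, prefix, mediator_names=None):
    """Write stage diagnostics: the screening ranking and, for the debiased
    pipeline, per-mediator raw-vs-debiased coefficients.

    Returns the list of paths written.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    det = result.details
    k = len(result.table)
    names = (np.asarray(mediator_names) if mediator_names is not None
             else np.arange(k))
    paths = []
    if "screen_scores" in det:
        rank = np.empty(k, dtype=int)
        rank[np.asarray(det["screen_ranked"])] = np.arange(1, k + 1)
        kept = np.zeros(k, dtype=bool)
        kept[np.asarray(det["kept"])] = True
        screen = pd.DataFrame(
            {"mediator_id": names, "score": det["screen_scores"],
             "rank": rank, "kept": kept}
        )
        path = prefix.with_suffix(".screen.tsv")
        screen.to_csv(path, sep="\t", index=False)
        paths.append(path)
    if "b_lasso" in det:
        kept_idx = np.asarray(det["kept"])
        sub = result.table.loc[kept_idx]
        diag = pd.DataFrame(
            {"mediator_id": names[kept_idx],
             "b_lasso": det["b_lasso"],
             "b_debiased": sub["b_hat"].to_numpy(),
             "se_b": sub["se_b"].to_numpy(),
             "p_b": sub["p_b"].to_numpy()}
        )
        path = prefix.with_suffix(".inference.tsv")
        diag.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
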