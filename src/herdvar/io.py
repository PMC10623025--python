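"""Plain-text readers and writers for the pipeline's artifacts.

Formats: pedigree CSV (``animal,sire,dam``; empty/0 = unknown), phenotype CSV
(one row per cow), chain-sample files (one row per stored draw, one column per
(co)variance element in row-major lower-triangle order, ``#``-prefixed header
naming columns), and posterior summary tables (CSV with columns
``parameter,mean,mode,median,sd,hpd_lower,hpd_upper,ess,mce,geweke_z``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gibbs import ChainConfig, CovarianceSamples
from .pedigree import read_pedigree_csv  # noqa: F401  (re-export: io surface)
from .postgibbs import PosteriorSummary

SUMMARY_COLUMNS = [
    "parameter", "mean", "mode", "median", "sd",
    "hpd_lower", "hpd_upper", "ess", "mce", "geweke_z",
]


def write_phenotypes_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_phenotypes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_pedigree_csv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal,sire,dam\n")
        for r in records:
            fh.write(f"{r.animal},{r.sire or '0'},{r.dam or '0'}\n")


def _lower_triangle_labels(traits, prefix):
    labels = []
    for i, ti in enumerate(traits):
        for j in range(i + 1):
            labels.append(f"{prefix}[{ti},{traits[j]}]")
    return labels


def write_chain_samples(samples: CovarianceSamples, path) -> None:
    """Write stored draws: iteration, then G0 and R0 lower triangles row-major."""
    t = samples.G0.shape[1]
    traits = samples.traits or tuple(f"trait{i + 1}" for i in range(t))
    labels = (
        ["iteration"]
        + _lower_triangle_labels(traits, "G")
        + _lower_triangle_labels(traits, "R")
    )
    tril = np.tril_indices(t)
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(labels) + "\n")
        for it, g, r in zip(samples.iterations, samples.G0, samples.R0):
            vals = np.concatenate([g[tril], r[tril]])
            fh.write(str(int(it)) + "\t" + "\t".join(f"{v:.10g}" for v in vals) + "\n")


def read_chain_samples(path) -> CovarianceSamples:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("chain file must start with a '#' header line")
        labels = header[1:].split()
        body = np.loadtxt(fh, ndmin=2)
    n_tri = (len(labels) - 1) // 2
    t = int((np.sqrt(8 * n_tri + 1) - 1) / 2)
    traits = []
    for lab in labels[1 : 1 + n_tri]:
        name = lab[lab.index("[") + 1 : lab.index("]")].split(",")[0]
        if name not in traits:
            traits.append(name)
    tril = np.tril_indices(t)
    n = body.shape[0]
    G = np.zeros((n, t, t))
    R = np.zeros((n, t, t))
    for k in range(n):
        g = np.zeros((t, t))
        r = np.zeros((t, t))
        g[tril] = body[k, 1 : 1 + n_tri]
        r[tril] = body[k, 1 + n_tri : 1 + 2 * n_tri]
        G[k] = g + np.tril(g, -1).T
        R[k] = r + np.tril(r, -1).T
    return CovarianceSamples(
        G0=G, R0=R, iterations=body[:, 0].astype(np.int64), traits=tuple(traits)
    )


def summaries_to_frame(summaries: dict[str, PosteriorSummary]) -> pd.DataFrame:
    rows = []
    for name, s in summaries.items():
        row = {"parameter": name}
        row.update(s.as_row())
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary_csv(summaries: dict[str, PosteriorSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != SUMMARY_COLUMNS:
        raise ValueError("unexpected summary table columns")
    return df


def write_run_log(path, seed, filters=None, exclusions=None, extra=None) -> None:
    """Record the provenance of a run: seed, package versions, filters, counts."""
    import platform

    from . import __version__

    lines = [
        f"herdvar {__version__}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
        f"seed {seed}",
    ]
    if filters is not None:
        lines.append(f"filters {filters}")
    if exclusions is not None:
        for rule, count in exclusions.items():
            lines.append(f"excluded[{rule}] {count}")
    for k, v in (extra or {}).items():
        lines.append(f"{k} {v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
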