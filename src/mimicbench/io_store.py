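"""Reading/writing count tables and the hierarchical simulation store.

Count tables travel as TSV (features in rows by default, mOTUs style); all
simulation state -- original counts, per-repeat simulations with ground
truth, test indices and results -- is persisted in a single HDF5 file so
that every DA method sees byte-identical inputs.
"""

from __future__ import annotations

import json
import os
from typing import Dict, Iterable, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .containers import ConfoundedDataset, CountMatrix, GroundTruth, SimulatedDataset

__all__ = [
    "load_count_table",
    "load_metadata",
    "filter_features",
    "SimulationStore",
]


def load_count_table(path, features_in_rows: bool = True, strict: bool = True) -> CountMatrix:
    """Load a TSV count table into a :class:`CountMatrix`.

    Parameters
    ----------
    path
        TSV file with one header row and one id column.
    features_in_rows
        If False, the table is samples x features and is transposed on load.
    strict
        If True, fractional values are an error; otherwise they are floored.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"duplicate ids in {path}")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric body in {path}: {exc}") from exc
    if np.any(~np.isfinite(values)):
        raise ValueError(f"non-finite values in {path}")
    if np.any(values < 0):
        raise ValueError(f"negative counts in {path}")
    if np.any(values != np.floor(values)):
        if strict:
            raise ValueError(f"non-integer counts in {path} (pass strict=False to floor)")
        values = np.floor(values)
    if not features_in_rows:
        df = df.T
        values = values.T
    return CountMatrix(values.astype(np.int64), list(df.index), list(df.columns))


def load_metadata(path, sample_ids: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Load a sample-metadata TSV keyed by sample id, optionally reindexed."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    if sample_ids is not None:
        missing = set(sample_ids) - set(meta.index.astype(str))
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)[:5]}")
        meta = meta.loc[list(sample_ids)]
    return meta


def filter_features(
    cm: CountMatrix, prev_min: float = 0.05, relab_max_min: float = 1e-4
) -> CountMatrix:
    """Filter features by prevalence and maximum relative abundance.

    Keeps features present (count > 0) in at least ``prev_min`` of samples
    AND whose maximum per-sample relative abundance reaches ``relab_max_min``.
    With both thresholds at 0 the input is returned unchanged.
    """
    if not (0 <= prev_min <= 1 and 0 <= relab_max_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if prev_min == 0 and relab_max_min == 0:
        return cm
    prevalence = (cm.counts > 0).mean(axis=1)
    max_relab = cm.relative_abundance().max(axis=1)
    keep = (prevalence >= prev_min) & (max_relab >= relab_max_min)
    if not keep.any():
        raise ValueError(
            "filtering removed all features "
            f"(prev_min={prev_min}, relab_max_min={relab_max_min}; "
            f"max prevalence {prevalence.max():.3f}, max relab {max_relab.max():.2e})"
        )
    return CountMatrix(
        cm.counts[keep],
        [f for f, k in zip(cm.feature_ids, keep) if k],
        list(cm.sample_ids),
    )


# ---------------------------------------------------------------------------
# HDF5 store
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _truth_to_json(truth: GroundTruth) -> str:
    return json.dumps(
        {
            "features": truth.features,
            "direction": truth.direction,
            "abundance_scale": truth.abundance_scale,
            "prev_shift": truth.prev_shift,
            "gfc": truth.gfc,
            "rejected": truth.rejected,
        }
    )


def _truth_from_json(s: str) -> GroundTruth:
    d = json.loads(s)
    return GroundTruth(
        features=d["features"],
        direction={k: int(v) for k, v in d["direction"].items()},
        abundance_scale={k: float(v) for k, v in d["abundance_scale"].items()},
        prev_shift={k: float(v) for k, v in d["prev_shift"].items()},
        gfc={k: float(v) for k, v in d["gfc"].items()},
        rejected=d["rejected"],
    )


class SimulationStore:
    """Hierarchical (HDF5) store for one benchmarking project.

    Layout::

        /original/{counts,feature_ids,sample_ids}
        /sim/<key>/{counts,feature_ids,sample_ids,labels,truth[,confounder,confounder_truth]}
        /test_idx/<size>/<subsample>
        /results/<name>

    Every simulation group records its full parameterization (JSON) and seed,
    and a write->read round trip is the identity on counts, labels, indices
    and ground truth.
    """

    def __init__(self, path, mode: str = "a"):
        self.path = os.fspath(path)
        self._file = h5py.File(self.path, mode)

    def close(self) -> None:
        self._file.close()

    def __enter__(self) -> "SimulationStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- original data ------------------------------------------------------

    def save_original(self, cm: CountMatrix) -> None:
        if "original" in self._file:
            raise KeyError("original data already stored")
        g = self._file.create_group("original")
        self._write_cm(g, cm)

    def load_original(self) -> CountMatrix:
        if "original" not in self._file:
            raise KeyError("no original data in store")
        return self._read_cm(self._file["original"])

    # -- simulations --------------------------------------------------------

    def save_simulation(self, dataset, key: str) -> None:
        """Persist a SimulatedDataset or ConfoundedDataset under ``key``."""
        full = f"sim/{key}"
        if full in self._file:
            raise KeyError(f"simulation key exists: {key}")
        g = self._file.create_group(full)
        if isinstance(dataset, ConfoundedDataset):
            base = dataset.base
            g.create_dataset("confounder", data=np.asarray(dataset.confounder, dtype=np.int8))
            g.create_dataset(
                "confounder_truth", data=_truth_to_json(dataset.confounder_truth), dtype=_STR
            )
            if dataset.bias is not None:
                g.attrs["bias"] = float(dataset.bias)
        else:
            base = dataset
        self._write_cm(g, base.cm)
        g.create_dataset("labels", data=np.asarray(base.labels, dtype=np.int8))
        g.create_dataset("truth", data=_truth_to_json(base.truth), dtype=_STR)
        if base.seed is not None:
            g.attrs["seed"] = int(base.seed)
        g.attrs["params"] = json.dumps(base.params)

    def load_simulation(self, key: str):
        full = f"sim/{key}"
        if full not in self._file:
            raise KeyError(f"no such simulation: {key}")
        g = self._file[full]
        cm = self._read_cm(g)
        base = SimulatedDataset(
            cm=cm,
            labels=g["labels"][()],
            truth=_truth_from_json(g["truth"][()].decode()),
            seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
            params=json.loads(g.attrs.get("params", "{}")),
        )
        if "confounder" in g:
            return ConfoundedDataset(
                base=base,
                confounder=g["confounder"][()],
                confounder_truth=_truth_from_json(g["confounder_truth"][()].decode()),
                bias=float(g.attrs["bias"]) if "bias" in g.attrs else None,
            )
        return base

    def simulation_keys(self) -> List[str]:
        return sorted(self._file["sim"].keys()) if "sim" in self._file else []

    # -- test indices -------------------------------------------------------

    def save_test_indices(self, indices: Dict[Tuple[int, int], np.ndarray]) -> None:
        for (size, rep), idx in indices.items():
            name = f"test_idx/{size}/{rep}"
            if name in self._file:
                raise KeyError(f"test indices exist: {name}")
            self._file.create_dataset(name, data=np.asarray(idx, dtype=np.int64))

    def load_test_indices(self, size: int, rep: int) -> np.ndarray:
        name = f"test_idx/{size}/{rep}"
        if name not in self._file:
            raise KeyError(f"no such test indices: size={size}, rep={rep}")
        return self._file[name][()]

    # -- results ------------------------------------------------------------

    def save_results(self, name: str, df: pd.DataFrame) -> None:
        key = f"results/{name}"
        if key in self._file:
            del self._file[key]
        self._file.create_dataset(key, data=df.to_csv(sep="\t", index=False), dtype=_STR)

    def load_results(self, name: str) -> pd.DataFrame:
        import io

        key = f"results/{name}"
        if key not in self._file:
            raise KeyError(f"no such results: {name}")
        return pd.read_csv(io.StringIO(self._file[key][()].decode()), sep="\t")

    def result_names(self) -> List[str]:
        return sorted(self._file["results"].keys()) if "results" in self._file else []

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _write_cm(g: h5py.Group, cm: CountMatrix) -> None:
        g.create_dataset("counts", data=cm.counts, compression="gzip", compression_opts=4)
        g.create_dataset("feature_ids", data=np.array(cm.feature_ids, dtype=_STR))
        g.create_dataset("sample_ids", data=np.array(cm.sample_ids, dtype=_STR))

    @staticmethod
    def _read_cm(g: h5py.Group) -> CountMatrix:
        return CountMatrix(
            g["counts"][()],
            [s.decode() for s in g["feature_ids"][()]],
            [s.decode() for s in g["sample_ids"][()]],
        )


def export_results_tsv(df: pd.DataFrame, path) -> None:
    """Write a long-format results table as TSV."""
    df.to_csv(path, sep="\t", index=False)
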