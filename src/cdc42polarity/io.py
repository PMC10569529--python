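"""Plain-text readers/writers for snapshots, series and run metadata.

Everything is tab-separated text so that runs can be archived, diffed and
re-analyzed without the package: one row per particle for snapshots
(t, species, x, y[, z]), one row per sample for K and count series.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


def write_snapshots(traj, path):
    """All recorded particle positions as tabular text."""
    rows = []
    for st in traj.snapshots:
        names = np.asarray(st.species_names)[st.species]
        for k in range(len(names)):
            rows.append((st.t, names[k], *st.positions[k]))
    dim = traj.snapshots[0].positions.shape[1] if traj.snapshots else 2
    cols = ["t", "species", "x", "y"] + (["z"] if dim == 3 else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_snapshot_points(path, species=None, t=None):
    """Positions from a snapshot table, optionally filtered by species/time."""
    df = pd.read_csv(path, sep="\t")
    if species is not None:
        if isinstance(species, str):
            species = (species,)
        df = df[df["species"].isin(species)]
    if t is not None:
        df = df[np.isclose(df["t"], t)]
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    return df[cols].to_numpy()


def write_k_series(times, K, geometry_mode, path):
    from .ripley import classify_state

    df = pd.DataFrame(
        {"t": times, "K": K, "state": [classify_state(k, geometry_mode) for k in K]}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_k_series(path):
    df = pd.read_csv(path, sep="\t")
    return df["t"].to_numpy(), df["K"].to_numpy()


def write_counts(counts_df: pd.DataFrame, path):
    counts_df.rename_axis("t").to_csv(path, sep="\t")


def write_count_series(times, n_clusters, path):
    pd.DataFrame({"t": times, "n_clusters": n_clusters}).to_csv(path, sep="\t", index=False)


def read_count_series(path):
    """Experimental-style cluster-count series (t, n_clusters)."""
    df = pd.read_csv(path, sep="\t")
    return df["t"].to_numpy(float), df["n_clusters"].to_numpy(int)


def _plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_meta(meta: dict, path):
    """Run metadata (seed, parameters, protocol) as YAML."""
    Path(path).write_text(yaml.safe_dump(_plain(meta), sort_keys=False))


def write_ring_profile(profile, path):
    df = pd.DataFrame(
        {
            "ring": np.arange(len(profile.mean_nM)),
            "theta_deg": profile.theta_centers,
            "mean_nM": profile.mean_nM,
            "std_nM": profile.std_nM,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
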