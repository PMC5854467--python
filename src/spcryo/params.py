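"""Frealign-style plain-text per-particle parameter tables.

Columns: index, psi, theta, phi (degrees), shift_x, shift_y (Å), mag,
defocus1, defocus2 (Å), astig_angle (degrees), phase_shift (radians),
occupancy, logp, sigma, score.  Values are written with full float
precision (%.17g) so a write/read round trip is bit-stable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLUMNS = ["index", "psi", "theta", "phi", "shift_x", "shift_y", "mag",
           "defocus1", "defocus2", "astig_angle", "phase_shift",
           "occupancy", "logp", "sigma", "score"]


def empty_table(n: int) -> pd.DataFrame:
    """A fresh table for n particles with neutral defaults."""
    df = pd.DataFrame({c: np.zeros(n) for c in COLUMNS})
    df["index"] = np.arange(1, n + 1)
    df["mag"] = 1.0
    df["occupancy"] = 100.0
    df["sigma"] = 1.0
    return df


def from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Build a parameter table from a synthetic-data ground-truth frame."""
    df = empty_table(len(truth))
    for col in ("phi", "theta", "psi", "shift_x", "shift_y"):
        if col in truth:
            df[col] = np.asarray(truth[col], dtype=float)
    if "defocus" in truth:
        df["defocus1"] = np.asarray(truth["defocus"], dtype=float)
        df["defocus2"] = np.asarray(truth["defocus"], dtype=float)
    if "sigma_noise" in truth:
        df["sigma"] = np.where(truth["sigma_noise"] > 0,
                               truth["sigma_noise"], 1.0)
    return df


def write_params(path, df: pd.DataFrame) -> None:
    df = df[COLUMNS]
    with open(path, "w") as fh:
        fh.write("# " + " ".join(COLUMNS) + "\n")
        for _, row in df.iterrows():
            fields = [f"{int(row['index']):d}"]
            fields += [f"{row[c]:.17g}" for c in COLUMNS[1:]]
            fh.write(" ".join(fields) + "\n")


def read_params(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", comment=None, skiprows=1,
                     names=COLUMNS, header=None,
                     float_precision="round_trip")
    # all-zero columns would otherwise be inferred as integers
    for col in COLUMNS[1:]:
        df[col] = df[col].astype(float)
    df["index"] = df["index"].astype(int)
    return df
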