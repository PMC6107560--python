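"""Plain-text readers and writers for every pipeline artifact.

All tabular artifacts are CSV with headers; colony ground truth round-trips
as JSON. Timestamps are seconds from the start of the day; days are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import require_columns
from .events import ForagingEvent, GroupByIndividual
from .song import ElementTrace
from .synthetic import ColonyTruth

STREAM_COLUMNS = ["bird_id", "aviary_id", "feeder_id", "day", "time_s"]


def write_visit_stream(stream: pd.DataFrame, path) -> None:
    require_columns(stream, STREAM_COLUMNS, "visit stream")
    stream[STREAM_COLUMNS].to_csv(path, index=False)


def read_visit_stream(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    require_columns(df, STREAM_COLUMNS, f"visit stream {path}")
    return df


def write_truth(colony: ColonyTruth, path) -> None:
    payload = {
        "birds": colony.birds.to_dict(orient="records"),
        "affinity": {
            str(a): {"roster": list(M.index), "matrix": M.to_numpy().tolist()}
            for a, M in colony.affinity.items()
        },
        "gregariousness": colony.gregariousness.to_dict(),
        "true_tutor": colony.true_tutor,
        "true_copy_noise": colony.true_copy_noise,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> ColonyTruth:
    payload = json.loads(Path(path).read_text())
    affinity = {
        int(a): pd.DataFrame(
            np.asarray(entry["matrix"]), index=entry["roster"], columns=entry["roster"]
        )
        for a, entry in payload["affinity"].items()
    }
    return ColonyTruth(
        birds=pd.DataFrame(payload["birds"]),
        affinity=affinity,
        gregariousness=pd.Series(payload["gregariousness"], name="gregariousness"),
        true_tutor=payload["true_tutor"],
        true_copy_noise=payload["true_copy_noise"],
    )


def write_song_traces(motifs: dict, path) -> None:
    """Long-format element-feature table: bird, motif, element, time, features."""
    rows = []
    for bird in sorted(motifs):
        for m, motif in enumerate(motifs[bird]):
            for el in motif:
                for t, frame in enumerate(el.values):
                    rows.append((bird, m, el.element_idx, t, *frame))
    n_feat = len(rows[0]) - 4 if rows else 0
    cols = ["bird_id", "motif_idx", "element_idx", "t_idx"] + [
        f"feature_{i + 1}" for i in range(n_feat)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_song_traces(path) -> dict:
    df = pd.read_csv(path)
    require_columns(df, ["bird_id", "motif_idx", "element_idx", "t_idx"], path)
    feats = [c for c in df.columns if c.startswith("feature_")]
    motifs: dict = {}
    for bird, bdf in df.groupby("bird_id"):
        renditions = []
        for m, mdf in bdf.groupby("motif_idx"):
            motif = []
            for e, edf in mdf.groupby("element_idx"):
                edf = edf.sort_values("t_idx")
                motif.append(ElementTrace(edf[feats].to_numpy(), str(bird), int(m), int(e)))
            renditions.append(motif)
        motifs[str(bird)] = renditions
    return motifs


def write_events(events, path) -> None:
    rows = [
        (e.aviary_id, e.feeder_id, e.day, e.start_s, e.end_s,
         ";".join(sorted(e.members)))
        for e in events
    ]
    pd.DataFrame(
        rows, columns=["aviary_id", "feeder_id", "day", "start_s", "end_s", "members"]
    ).to_csv(path, index=False)


def read_events(path) -> list:
    df = pd.read_csv(path)
    return [
        ForagingEvent(
            int(r.aviary_id), int(r.feeder_id), int(r.day),
            float(r.start_s), float(r.end_s), frozenset(str(r.members).split(";")),
        )
        for r in df.itertuples()
    ]


def write_gbis(gbis: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (a, d), gbi in gbis.items():
        df = pd.DataFrame(gbi.matrix, columns=list(gbi.roster))
        df.insert(0, "feeder_id", gbi.feeders)
        df.insert(1, "start_s", gbi.starts)
        df.insert(2, "end_s", gbi.ends)
        df.to_csv(outdir / f"gbi_a{a}_d{d:02d}.csv", index=False)


def write_sri_long(matrices: dict, path) -> None:
    rows = []
    for (a, d), M in sorted(matrices.items()):
        roster = list(M.index)
        for i, bi in enumerate(roster):
            for bj in roster[i + 1:]:
                rows.append((a, d, bi, bj, float(M.loc[bi, bj])))
    pd.DataFrame(
        rows, columns=["aviary_id", "day", "bird_i", "bird_j", "sri"]
    ).to_csv(path, index=False)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_rankings(rankings: dict, path) -> None:
    rows = []
    for son, r in sorted(rankings.items()):
        for rec in r.table.itertuples():
            rows.append((son, rec.candidate, rec.dissimilarity, rec.rank,
                         int(r.father_rank == rec.rank if r.father_rank else 0)))
    pd.DataFrame(
        rows, columns=["juvenile", "candidate", "dissimilarity", "rank", "is_father"]
    ).to_csv(path, index=False)
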