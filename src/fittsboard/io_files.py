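"""Readers and writers for the pipeline's file formats.

All JSON is written with sorted keys and floats rounded to six decimals so
that repeated runs with the same seed produce byte-identical files.  Trial
logs and session logs are plain CSV.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .characterization import FittsFit, FittsProfile, TrialRecord
from .geometry import AngularBinScheme, GridSpec, KeyPosition
from .layout_gen import Layout
from .text import Alphabet
from .user_sim import SessionLog, UserModel

__all__ = [
    "RunConfig",
    "write_json",
    "profile_to_dict",
    "profile_from_dict",
    "write_profile",
    "read_profile",
    "layout_to_dict",
    "layout_from_dict",
    "write_layout",
    "read_layout",
    "user_to_dict",
    "user_from_dict",
    "write_user",
    "read_user",
    "write_trials",
    "read_trials",
    "write_flow",
    "read_flow",
    "write_session",
]

_FLOAT_DECIMALS = 6

TRIAL_HEADER = [
    "trial_id", "from_row", "from_col", "to_row", "to_col",
    "click_from_x", "click_from_y", "click_to_x", "click_to_y",
    "distance_px", "movement_time_s", "angle_deg", "bin", "id_bits",
    "n_click_attempts", "success",
]


@dataclass(frozen=True)
class RunConfig:
    """Bundle of pipeline settings for a reproducible run."""

    grid: GridSpec = field(default_factory=GridSpec)
    scheme: AngularBinScheme = field(default_factory=AngularBinScheme)
    seed_cfg: "SeedConfig" = None  # type: ignore[assignment]
    alphabet: Alphabet = field(default_factory=Alphabet)
    corpus_path: str | None = None
    restarts: int = 32
    rng_seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.seed_cfg is None:
            from .characterization import SeedConfig

            object.__setattr__(self, "seed_cfg", SeedConfig(rng_seed=self.rng_seed))

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "scheme": self.scheme.to_dict(),
            "seed_cfg": vars(self.seed_cfg).copy(),
            "alphabet": self.alphabet.chars,
            "corpus_path": self.corpus_path,
            "restarts": self.restarts,
            "rng_seed": self.rng_seed,
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .characterization import SeedConfig

        return cls(
            grid=GridSpec.from_dict(d["grid"]),
            scheme=AngularBinScheme.from_dict(d["scheme"]),
            seed_cfg=SeedConfig(**d["seed_cfg"]),
            alphabet=Alphabet(d["alphabet"]),
            corpus_path=d.get("corpus_path"),
            restarts=int(d.get("restarts", 32)),
            rng_seed=int(d.get("rng_seed", 0)),
            output_dir=d.get("output_dir", "."),
        )


def _round_floats(obj):
    if isinstance(obj, float):
        return round(obj, _FLOAT_DECIMALS)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).write_text(
        json.dumps(_round_floats(obj), sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )


def _read_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


# -- FittsProfile ----------------------------------------------------------


def profile_to_dict(profile: FittsProfile) -> dict:
    return {
        "scheme": profile.scheme.to_dict(),
        "grid": profile.grid.to_dict(),
        "fits": [
            {
                "bin": f.bin,
                "a_s": f.a_s,
                "b_s_per_bit": f.b_s_per_bit,
                "r2": f.r2,
                "n": f.n,
                "residual_sd_s": f.residual_sd_s,
                "valid": f.valid,
            }
            for f in profile.fits
        ],
        "provenance": profile.provenance,
    }


def profile_from_dict(d: dict) -> FittsProfile:
    fits = tuple(
        FittsFit(
            bin=int(f["bin"]),
            a_s=float(f["a_s"]),
            b_s_per_bit=float(f["b_s_per_bit"]),
            r2=float(f["r2"]),
            n=int(f["n"]),
            residual_sd_s=float(f["residual_sd_s"]),
            valid=bool(f["valid"]),
        )
        for f in sorted(d["fits"], key=lambda f: f["bin"])
    )
    return FittsProfile(
        scheme=AngularBinScheme.from_dict(d["scheme"]),
        grid=GridSpec.from_dict(d["grid"]),
        fits=fits,
        provenance=d.get("provenance", ""),
    )


def write_profile(profile: FittsProfile, path) -> None:
    write_json(profile_to_dict(profile), path)


def read_profile(path) -> FittsProfile:
    return profile_from_dict(_read_json(path))


# -- Layout ----------------------------------------------------------------


def layout_to_dict(layout: Layout) -> dict:
    return {
        "label": layout.label,
        "grid": layout.grid.to_dict(),
        "energy": layout.energy,
        "keys": [
            {
                "char": ch,
                "row": k.row,
                "col": k.col,
                "center_x": k.center[0],
                "center_y": k.center[1],
            }
            for ch, k in sorted(layout.assignment.items())
        ],
    }


def layout_from_dict(d: dict) -> Layout:
    grid = GridSpec.from_dict(d["grid"])
    assignment = {e["char"]: grid.key(int(e["row"]), int(e["col"])) for e in d["keys"]}
    energy = d.get("energy")
    return Layout(
        assignment=assignment,
        grid=grid,
        label=d.get("label", ""),
        energy=None if energy is None else float(energy),
    )


def write_layout(layout: Layout, path) -> None:
    write_json(layout_to_dict(layout), path)


def read_layout(path) -> Layout:
    return layout_from_dict(_read_json(path))


# -- UserModel -------------------------------------------------------------


def user_to_dict(user: UserModel) -> dict:
    return {
        "scheme": user.scheme.to_dict(),
        "a_s": [float(v) for v in user.a_s],
        "b_s_per_bit": [float(v) for v in user.b_s_per_bit],
        "noise_sd_s": user.noise_sd_s,
        "miss_prob": user.miss_prob,
        "mt_floor_s": user.mt_floor_s,
        "rng_seed": user.rng_seed,
    }


def user_from_dict(d: dict) -> UserModel:
    return UserModel(
        a_s=np.array(d["a_s"], dtype=float),
        b_s_per_bit=np.array(d["b_s_per_bit"], dtype=float),
        noise_sd_s=float(d["noise_sd_s"]),
        miss_prob=float(d["miss_prob"]),
        mt_floor_s=float(d["mt_floor_s"]),
        rng_seed=int(d["rng_seed"]),
        scheme=AngularBinScheme.from_dict(d["scheme"]),
    )


def write_user(user: UserModel, path) -> None:
    write_json(user_to_dict(user), path)


def read_user(path) -> UserModel:
    return user_from_dict(_read_json(path))


# -- trial log CSV ---------------------------------------------------------


def write_trials(trials, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRIAL_HEADER)
        for t in trials:
            w.writerow(
                [
                    t.trial_id,
                    t.from_key.row, t.from_key.col, t.to_key.row, t.to_key.col,
                    repr(float(t.click_from[0])), repr(float(t.click_from[1])),
                    repr(float(t.click_to[0])), repr(float(t.click_to[1])),
                    repr(float(t.distance_px)), repr(float(t.movement_time_s)),
                    "" if t.angle_deg is None else repr(float(t.angle_deg)),
                    t.bin, repr(float(t.id_bits)), t.n_click_attempts, int(t.success),
                ]
            )


def read_trials(path, grid: GridSpec | None = None) -> list[TrialRecord]:
    """Parse a trial-log CSV back into records.

    Raises
    ------
    ValueError
        Naming the 1-based CSV line on any malformed row.
    """
    grid = grid or GridSpec()
    trials: list[TrialRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != TRIAL_HEADER:
            raise ValueError(f"unexpected trial log header in {path}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(TRIAL_HEADER):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(TRIAL_HEADER)} fields, got {len(row)}"
                )
            try:
                from_key = grid.key(int(row[1]), int(row[2]))
                to_key = grid.key(int(row[3]), int(row[4]))
                distance = float(row[9])
                trials.append(
                    TrialRecord(
                        trial_id=int(row[0]),
                        from_key=from_key,
                        to_key=to_key,
                        click_from=(float(row[5]), float(row[6])),
                        click_to=(float(row[7]), float(row[8])),
                        distance_px=distance,
                        movement_time_s=float(row[10]),
                        angle_deg=None if row[11] == "" else float(row[11]),
                        bin=int(row[12]),
                        id_bits=float(row[13]),
                        n_click_attempts=int(row[14]),
                        success=bool(int(row[15])),
                        level=round(distance / grid.key_width_px),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return trials


# -- flow matrix CSV -------------------------------------------------------


def write_flow(flow: np.ndarray, path, alphabet: Alphabet = Alphabet()) -> None:
    chars = list(alphabet)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + chars)
        for i, ch in enumerate(chars):
            w.writerow([ch] + [f"{v:g}" for v in flow[i]])


def read_flow(path, alphabet: Alphabet = Alphabet()) -> np.ndarray:
    chars = list(alphabet)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[1:] != chars:
            raise ValueError(f"{path}: flow header does not match the alphabet")
        flow = np.zeros((len(chars), len(chars)))
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(chars) + 1:
                raise ValueError(f"{path}: line {lineno}: wrong field count")
            i = alphabet.index(row[0])
            flow[i] = [float(v) for v in row[1:]]
    return flow


# -- session log CSV -------------------------------------------------------


def write_session(session: SessionLog, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["prompt", "intended", "selected", "movement_time_s", "success"])
        for s in session.selections:
            w.writerow([session.prompt, s.intended, s.selected, f"{s.movement_time_s:.6f}", int(s.success)])
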