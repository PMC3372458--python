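"""Variant feature encodings: mut, E, Wx and GO blocks.

Segment order in every composed vector is fixed as [mut | E | Wx | GO]:

* ``mut`` — 20 values, -1 at the wild-type residue index, +1 at the
  mutant index, 0 elsewhere;
* ``E`` — 4 values from the PSSM row at the mutated position: the
  wild-type and mutant substitution log-odds (scaled by 1/10) and the
  wild-type and mutant observed frequencies (scaled to [0, 1]);
* ``Wx`` — an x-position profile window centred on the mutation,
  20*x observed frequencies scaled to [0, 1], zero-padded where the
  window crosses a sequence end;
* ``GO`` — the protein's 3 per-aspect GO-scores (C, F, P).

The named configurations mirror the ablation series of the method:
``mut_E_W1``, ``mut_E_W5``, ``OnlyGO``, ``mut_GO_E``, ``mut_GO_E_W1``,
``mut_GO_E_W5``, ``mut_GO``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mutgo.dataset_io import AA_INDEX, PssmProfile, VariantRecord
from mutgo.go_scoring import GoScore


@dataclass(frozen=True)
class EncodingConfig:
    name: str
    use_mut: bool = False
    use_E: bool = False
    window_x: int = 0  # total window width in residues; 0 = no window
    use_go: bool = False

    def __post_init__(self) -> None:
        if self.window_x < 0:
            raise ValueError("window_x must be >= 0")
        if self.window_x and self.window_x % 2 == 0:
            raise ValueError("window_x must be odd (centred window)")

    @property
    def n_features(self) -> int:
        return (
            20 * self.use_mut + 4 * self.use_E + 20 * self.window_x + 3 * self.use_go
        )

    @property
    def needs_profile(self) -> bool:
        return self.use_E or self.window_x > 0


ENCODINGS: dict[str, EncodingConfig] = {
    cfg.name: cfg
    for cfg in (
        EncodingConfig("mut_E_W1", use_mut=True, use_E=True, window_x=1),
        EncodingConfig("mut_E_W5", use_mut=True, use_E=True, window_x=5),
        EncodingConfig("OnlyGO", use_go=True),
        EncodingConfig("mut_GO_E", use_mut=True, use_go=True, use_E=True),
        EncodingConfig("mut_GO_E_W1", use_mut=True, use_go=True, use_E=True, window_x=1),
        EncodingConfig("mut_GO_E_W5", use_mut=True, use_go=True, use_E=True, window_x=5),
        EncodingConfig("mut_GO", use_mut=True, use_go=True),
        # not in the published series, useful as an ablation control
        EncodingConfig("mut", use_mut=True),
    )
}


def get_encoding(name: str) -> EncodingConfig:
    try:
        return ENCODINGS[name]
    except KeyError:
        raise ValueError(
            f"unknown encoding {name!r}; known: {sorted(ENCODINGS)}"
        ) from None


def encode_mut(variant: VariantRecord) -> np.ndarray:
    """Substitution indicator: -1 at wild type, +1 at mutant."""
    vec = np.zeros(20)
    vec[AA_INDEX[variant.wt_aa]] = -1.0
    vec[AA_INDEX[variant.mut_aa]] = 1.0
    return vec


def encode_E(variant: VariantRecord, profile: PssmProfile) -> np.ndarray:
    """The 4 profile columns of the mutated position: wt/mut log-odds, wt/mut freqs."""
    if not 1 <= variant.position <= profile.length:
        raise ValueError(
            f"position {variant.position} outside profile "
            f"{profile.protein_id} (length {profile.length})"
        )
    return np.array(
        [
            profile.logodds_at(variant.position, variant.wt_aa) / 10.0,
            profile.logodds_at(variant.position, variant.mut_aa) / 10.0,
            profile.freq_at(variant.position, variant.wt_aa) / 100.0,
            profile.freq_at(variant.position, variant.mut_aa) / 100.0,
        ]
    )


def encode_window(variant: VariantRecord, profile: PssmProfile, x: int) -> np.ndarray:
    """Profile frequency window of width x centred on the mutated position.

    Positions outside [1, length] contribute 20 zeros each.
    """
    if x < 1 or x % 2 == 0:
        raise ValueError("window width x must be odd and >= 1")
    if not 1 <= variant.position <= profile.length:
        raise ValueError(
            f"position {variant.position} outside profile "
            f"{profile.protein_id} (length {profile.length})"
        )
    half = (x - 1) // 2
    blocks = []
    for pos in range(variant.position - half, variant.position + half + 1):
        if 1 <= pos <= profile.length:
            blocks.append(np.asarray(profile.freqs[pos - 1]) / 100.0)
        else:
            blocks.append(np.zeros(20))
    return np.concatenate(blocks)


def encode_variant(
    variant: VariantRecord,
    config: EncodingConfig,
    profile: PssmProfile | None = None,
    goscore: GoScore | None = None,
) -> np.ndarray:
    segments: list[np.ndarray] = []
    if config.use_mut:
        segments.append(encode_mut(variant))
    if config.use_E:
        if profile is None:
            raise ValueError(f"encoding {config.name} needs a profile")
        segments.append(encode_E(variant, profile))
    if config.window_x:
        if profile is None:
            raise ValueError(f"encoding {config.name} needs a profile")
        segments.append(encode_window(variant, profile, config.window_x))
    if config.use_go:
        if goscore is None:
            raise ValueError(f"encoding {config.name} needs GO-scores")
        segments.append(np.asarray(goscore.as_vector(), dtype=float))
    vec = np.concatenate(segments) if segments else np.zeros(0)
    assert vec.shape == (config.n_features,)
    return vec


def build_design_matrix(
    variants: Sequence[VariantRecord],
    config: EncodingConfig,
    profiles: Mapping[str, PssmProfile] | None = None,
    goscores: Mapping[str, GoScore] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature vectors in variant order; labels as {CANCER: 1, other: 0}.

    GO-scores must come from tables fitted without the test fold — the
    caller owns fold bookkeeping; :mod:`mutgo.svm` asserts it.
    """
    rows = []
    for v in variants:
        profile = None
        if config.needs_profile:
            if profiles is None or v.protein_id not in profiles:
                raise ValueError(
                    f"encoding {config.name} needs a profile for {v.protein_id}"
                )
            profile = profiles[v.protein_id]
        goscore = None
        if config.use_go:
            if goscores is None or v.protein_id not in goscores:
                raise ValueError(
                    f"encoding {config.name} needs a GO-score for {v.protein_id}"
                )
            goscore = goscores[v.protein_id]
        rows.append(encode_variant(v, config, profile=profile, goscore=goscore))
    X = np.vstack(rows) if rows else np.zeros((0, config.n_features))
    y = np.array([1 if v.label.value == "CANCER" else 0 for v in variants])
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    return X, y
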