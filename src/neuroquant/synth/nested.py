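"""Nested (animal / replicate) dataset generator.

Emulates the hierarchical designs of slice-physiology and imaging studies:
two genotype groups, several animals per group, several technical replicates
(cells, slices, dendrite segments) per animal.  Each value is

    value = group mean + animal effect + replicate noise

with the animal effect ~ N(0, animal_sd^2) and replicate noise
~ N(0, replicate_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NestedDataSpec", "generate_nested_dataset"]


@dataclass(frozen=True)
class NestedDataSpec:
    """Ground-truth description of a two-group nested dataset.

    ``replicates_per_animal`` may be a single integer (balanced design) or a
    sequence with one count per animal (group A animals first).
    """

    n_animals_per_group: tuple[int, int] = (6, 6)
    replicates_per_animal: int | tuple[int, ...] = 3
    group_means: tuple[float, float] = (0.0, 0.0)
    animal_sd: float = 1.0
    replicate_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if min(self.n_animals_per_group) < 2:
            raise ValueError("at least 2 animals per group are required")
        if self.animal_sd < 0 or self.replicate_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        reps = self.replicates_per_animal
        n_total = sum(self.n_animals_per_group)
        if isinstance(reps, int):
            if reps < 1:
                raise ValueError("replicates_per_animal must be >= 1")
        else:
            if len(reps) != n_total:
                raise ValueError(
                    f"need one replicate count per animal ({n_total}), got {len(reps)}"
                )
            if min(reps) < 1:
                raise ValueError("every animal needs at least one replicate")


def generate_nested_dataset(spec: NestedDataSpec) -> pd.DataFrame:
    """Render a nested dataset as a long-format table (group, animal, value)."""
    rng = np.random.default_rng(spec.seed)
    n_total = sum(spec.n_animals_per_group)
    reps = spec.replicates_per_animal
    if isinstance(reps, int):
        reps = (reps,) * n_total

    rows = []
    animal_idx = 0
    for g_label, g_mean, n_animals in zip(
        ("A", "B"), spec.group_means, spec.n_animals_per_group
    ):
        for _ in range(n_animals):
            effect = rng.normal(0.0, spec.animal_sd) if spec.animal_sd > 0 else 0.0
            n_rep = reps[animal_idx]
            noise = (
                rng.normal(0.0, spec.replicate_sd, size=n_rep)
                if spec.replicate_sd > 0
                else np.zeros(n_rep)
            )
            animal_id = f"{g_label}{animal_idx:03d}"
            for v in g_mean + effect + noise:
                rows.append((g_label, animal_id, float(v)))
            animal_idx += 1
    return pd.DataFrame(rows, columns=["group", "animal", "value"])
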