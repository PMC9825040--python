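"""Synthetic activity classes with congeneric series and planted cliffs.

Compounds are scaffold ⊕ substituent assemblies with one variable site:

    pKi(s, r) = baseline(s) + beta(s, r) + N(0, noise_sd^2)

Scaffold baselines are drawn from N(baseline_mean, baseline_sd^2). A
fraction of substituents is designated cliff-forming; on any given
scaffold such a substituent expresses the full ``cliff_effect`` potency
shift with probability ``cliff_penetrance`` and is otherwise silent.
Non-cliff substituents carry a mild effect drawn once per substituent
from N(0, noncliff_effect_sd^2) shared across scaffolds, plus a
scaffold-specific interaction term N(0, interaction_sd^2) drawn per
(scaffold, substituent) combination. Both the penetrance and the
interaction model context-dependent SAR: part of a compound's activity
is a fixed property of the individual compound rather than of its
substituent, which is what makes compound memorization (data leakage)
informative in randomly split pair data.

The shipped libraries keep every analog pair within the MMP size
filters by construction: scaffolds have >= 13 heavy atoms (at least
twice the largest substituent) and substituents 1-6 heavy atoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .chem import attach, heavy_atom_count
from .io import ActivityClass, CompoundRecord
from .mmp import MAX_SUBSTITUENT_ATOMS, MIN_CORE_ATOMS


def _load_library(name: str) -> list[str]:
    text = resources.files("mmpcliff.data").joinpath(name).read_text()
    return [line.split("\t")[0] for line in text.splitlines() if line.strip()]


def default_scaffold_library() -> list[str]:
    return _load_library("scaffolds.smi")


def default_substituent_library() -> list[str]:
    return _load_library("substituents.smi")


@dataclass(frozen=True)
class SyntheticClassConfig:
    n_scaffolds: int = 18
    substituents_per_scaffold: int = 14
    scaffold_library: tuple[str, ...] | None = None
    substituent_library: tuple[str, ...] | None = None
    cliff_fraction: float = 0.15
    cliff_effect: float = 3.0
    cliff_penetrance: float = 0.5
    noise_sd: float = 0.3
    baseline_mean: float = 6.5
    baseline_sd: float = 1.0
    noncliff_effect_sd: float = 0.5
    interaction_sd: float = 0.35
    seed: int = 0
    class_id: str = "SYN"

    def resolved_libraries(self) -> tuple[list[str], list[str]]:
        scaffolds = list(
            self.scaffold_library
            if self.scaffold_library is not None
            else default_scaffold_library()
        )
        subs = list(
            self.substituent_library
            if self.substituent_library is not None
            else default_substituent_library()
        )
        if not scaffolds or not subs:
            raise ValueError("scaffold and substituent libraries must be non-empty")
        sub_sizes = [heavy_atom_count(s) for s in subs]
        if min(sub_sizes) < 1 or max(sub_sizes) > MAX_SUBSTITUENT_ATOMS:
            raise ValueError("substituents must have 1..13 heavy atoms")
        for sc in scaffolds:
            n = heavy_atom_count(sc)
            if n < MIN_CORE_ATOMS or n < 2 * max(sub_sizes):
                raise ValueError(
                    f"scaffold {sc!r} too small for the MMP size filters"
                )
        if not 0.0 <= self.cliff_fraction <= 1.0:
            raise ValueError("cliff_fraction must be within [0, 1]")
        return scaffolds, subs


@dataclass
class GroundTruth:
    """Per-compound generative assignments for recovery tests."""

    scaffold_of: dict[str, int]
    substituent_of: dict[str, int]
    beta_of: dict[str, float]
    cliff_substituents: frozenset[int]
    expressed: dict[tuple[int, int], bool] = field(default_factory=dict)

    def carries_expressed_cliff(self, cid: str) -> bool:
        s, r = self.scaffold_of[cid], self.substituent_of[cid]
        return r in self.cliff_substituents and self.expressed.get((s, r), True)

    def is_planted_cliff(self, cid_a: str, cid_b: str) -> bool:
        """True iff the pair is same-scaffold and exactly one member
        carries an expressed cliff substituent."""
        if self.scaffold_of[cid_a] != self.scaffold_of[cid_b]:
            return False
        return self.carries_expressed_cliff(cid_a) != self.carries_expressed_cliff(cid_b)


def generate_class(config: SyntheticClassConfig) -> tuple[ActivityClass, GroundTruth]:
    scaffolds, subs = config.resolved_libraries()
    if config.n_scaffolds > len(scaffolds):
        raise ValueError("n_scaffolds exceeds scaffold library size")
    if config.substituents_per_scaffold > len(subs):
        raise ValueError("substituents_per_scaffold exceeds substituent library size")
    rng = np.random.default_rng(config.seed)

    scaffold_idx = rng.choice(len(scaffolds), size=config.n_scaffolds, replace=False)
    n_cliff = int(round(config.cliff_fraction * len(subs)))
    cliff_subs = frozenset(
        int(i) for i in rng.choice(len(subs), size=n_cliff, replace=False)
    )
    noncliff_beta = {
        r: float(rng.normal(0.0, config.noncliff_effect_sd))
        for r in range(len(subs))
        if r not in cliff_subs
    }
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, config.n_scaffolds)

    compounds, seen = [], set()
    truth = GroundTruth(
        scaffold_of={},
        substituent_of={},
        beta_of={},
        cliff_substituents=cliff_subs,
    )
    for si, s_idx in enumerate(scaffold_idx):
        sub_idx = rng.choice(
            len(subs), size=config.substituents_per_scaffold, replace=False
        )
        for r_idx in sorted(int(r) for r in sub_idx):
            if r_idx in cliff_subs:
                hit = bool(rng.random() < config.cliff_penetrance)
                truth.expressed[(int(s_idx), r_idx)] = hit
                beta = config.cliff_effect if hit else 0.0
            else:
                beta = noncliff_beta[r_idx] + float(
                    rng.normal(0.0, config.interaction_sd)
                )
            smiles = attach(scaffolds[int(s_idx)], subs[r_idx])
            if smiles in seen:  # same assembly from two library entries
                continue
            seen.add(smiles)
            cid = f"{config.class_id}_s{int(s_idx):02d}r{r_idx:02d}"
            pki = float(baselines[si] + beta + rng.normal(0.0, config.noise_sd))
            compounds.append(
                CompoundRecord(
                    compound_id=cid,
                    smiles=smiles,
                    pki=pki,
                    heavy_atom_count=heavy_atom_count(smiles),
                )
            )
            truth.scaffold_of[cid] = int(s_idx)
            truth.substituent_of[cid] = r_idx
            truth.beta_of[cid] = float(beta)

    cls = ActivityClass(
        class_id=config.class_id,
        compounds=compounds,
        metadata={"synthetic": True, "seed": config.seed},
    )
    return cls, truth


def generate_benchmark_suite(
    n_classes: int,
    base_config: SyntheticClassConfig | None = None,
    seed: int = 0,
) -> list[tuple[ActivityClass, GroundTruth]]:
    """Reproducible suite of classes jittered around a base configuration."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    base = base_config or SyntheticClassConfig()
    if n_classes == 1:
        return [generate_class(replace(base, class_id=f"{base.class_id}00"))]
    master = np.random.default_rng(seed)
    scaffolds, subs = base.resolved_libraries()
    out = []
    for i in range(n_classes):
        child_seed = int(master.integers(0, 2**31 - 1))
        n_sc = int(
            np.clip(base.n_scaffolds + master.integers(-3, 4), 2, len(scaffolds))
        )
        n_sub = int(
            np.clip(
                base.substituents_per_scaffold + master.integers(-2, 3),
                3,
                len(subs),
            )
        )
        frac = float(
            np.clip(base.cliff_fraction * master.uniform(0.8, 1.2), 0.0, 1.0)
        )
        cfg = replace(
            base,
            n_scaffolds=n_sc,
            substituents_per_scaffold=n_sub,
            cliff_fraction=frac,
            seed=child_seed,
            class_id=f"{base.class_id}{i:02d}",
        )
        out.append(generate_class(cfg))
    return out


# --- hand-built fixture -------------------------------------------------

#: two fused-ring scaffolds, noise-free baselines 6.0 and 7.0
FIXTURE_SCAFFOLDS = (
    "[*:1]c1ccc2c(c1)oc1ccccc12",  # dibenzofuran, 13 heavy atoms
    "[*:1]c1ccc2c(c1)[nH]c1ccccc12",  # carbazole, 13 heavy atoms
)
#: substituent -> true effect beta (log units); benzyloxy (8 heavy atoms)
#: is too large for a 13-atom core and can only pair through the
#: extended ether core it shares with methoxy
FIXTURE_SUBSTITUENTS = (
    ("[*:1]Cl", 0.0),
    ("[*:1]C", 0.5),
    ("[*:1]OC", -0.5),
    ("[*:1]F", 3.0),  # the planted cliff substituent
    ("[*:1]CC", 1.0),
    ("[*:1]OCc1ccccc1", 2.0),
)
FIXTURE_BASELINES = (6.0, 7.0)


def fixture_class() -> tuple[ActivityClass, GroundTruth]:
    """Deterministic 12-compound class (2 scaffolds x 6 substituents).

    Noise-free: pKi = baseline + beta exactly, so every pairwise potency
    difference is known in closed form.
    """
    compounds = []
    truth = GroundTruth(
        scaffold_of={},
        substituent_of={},
        beta_of={},
        cliff_substituents=frozenset({3}),
        expressed={(0, 3): True, (1, 3): True},
    )
    for si, (scaffold, baseline) in enumerate(
        zip(FIXTURE_SCAFFOLDS, FIXTURE_BASELINES)
    ):
        for ri, (sub, beta) in enumerate(FIXTURE_SUBSTITUENTS):
            cid = f"FIX_s{si}r{ri}"
            smiles = attach(scaffold, sub)
            compounds.append(
                CompoundRecord(
                    compound_id=cid,
                    smiles=smiles,
                    pki=baseline + beta,
                    heavy_atom_count=heavy_atom_count(smiles),
                )
            )
            truth.scaffold_of[cid] = si
            truth.substituent_of[cid] = ri
            truth.beta_of[cid] = beta
    cls = ActivityClass(
        class_id="FIXTURE", compounds=compounds, metadata={"synthetic": True}
    )
    assert len(cls) == 12
    return cls, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    import pandas as pd

    rows = [
        {
            "compound_id": cid,
            "scaffold": truth.scaffold_of[cid],
            "substituent": truth.substituent_of[cid],
            "beta": truth.beta_of[cid],
            "expressed_cliff": truth.carries_expressed_cliff(cid),
        }
        for cid in truth.scaffold_of
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _sigma_delta_null(noise_sd: float) -> float:
    """SD of the pairwise potency difference under the no-cliff null."""
    return math.sqrt(2.0) * noise_sd
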