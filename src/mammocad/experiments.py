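"""The four-arm experiment harness.

Four dataset variants of the same cohort are compared:

=====  ==================================  ============  ==========
arm    description                         augmentation  cheat sheet
=====  ==================================  ============  ==========
OS     original set                        no            no
DA     rotation-augmented training set     yes           no
CS     cheat-sheet encoded images          no            yes
DACS   augmentation + cheat sheet          yes           yes
=====  ==================================  ============  ==========

Each arm is trained and evaluated over several seeded runs (15 by default)
on a random 222/100 train/test split of the 322-image cohort, with 25% of
the training images held out for validation.  Cheat-sheet encoding happens
before the split (so test images carry frames too); augmentation happens
strictly after it, so no rotation of a test image can leak into training.
The split is redrawn per run, and within one run index the same split is
shared by all four arms so the arms are compared on identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cheatsheet as cs
from . import roi as roi_mod
from .augment import augment_training_set, resize
from .evaluate import run_metrics
from .mias import MammogramRecord, label_for
from .model import ModelConfig, build_model, train

__all__ = ["ArmConfig", "standard_arms", "make_split", "prepare_images",
           "build_arm", "run_experiment", "save_results", "load_results"]

#: Table of the four canonical arms: name -> (use_augmentation, use_cheatsheet)
ARM_FLAGS = {"OS": (False, False), "DA": (True, False),
             "CS": (False, True), "DACS": (True, True)}


@dataclass
class ArmConfig:
    name: str
    use_cheatsheet: bool
    use_augmentation: bool
    n_train: int = 222
    n_test: int = 100
    val_fraction: float = 0.25
    n_runs: int = 15
    base_seed: int = 0

    def validate(self) -> None:
        if self.name in ARM_FLAGS:
            aug, sheet = ARM_FLAGS[self.name]
            if (self.use_augmentation, self.use_cheatsheet) != (aug, sheet):
                raise ValueError(f"arm {self.name} must have augmentation="
                                 f"{aug}, cheatsheet={sheet}")


def standard_arms(n_train: int = 222, n_test: int = 100, n_runs: int = 15,
                  base_seed: int = 0) -> List[ArmConfig]:
    """The four canonical arms with shared sizing."""
    return [ArmConfig(name=k, use_augmentation=aug, use_cheatsheet=sheet,
                      n_train=n_train, n_test=n_test, n_runs=n_runs,
                      base_seed=base_seed)
            for k, (aug, sheet) in ARM_FLAGS.items()]


def make_split(ids: Sequence[str], n_train: int, n_test: int,
               seed: int) -> Tuple[List[str], List[str]]:
    """Seeded disjoint train/test split over original record ids."""
    ids = list(ids)
    if len(ids) < n_train + n_test:
        raise ValueError(f"cohort of {len(ids)} too small for "
                         f"{n_train}+{n_test} split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    test = [ids[i] for i in perm[:n_test]]
    trn = [ids[i] for i in perm[n_test:n_test + n_train]]
    return trn, test


def prepare_images(records: Sequence[MammogramRecord],
                   use_cheatsheet: bool,
                   chromosome: Optional[roi_mod.Chromosome] = None,
                   target: Tuple[int, int] = (100, 100),
                   biopsy_seed: int = 0,
                   enumerate_biopsy: bool = False) -> Dict[str, np.ndarray]:
    """ROI-extract (and optionally cheat-sheet-encode) every record.

    Encoding precedes the train/test split, so this runs once per cohort
    per arm flavour; the per-record biopsy seed is derived from
    ``biopsy_seed`` and the record index.
    """
    out: Dict[str, np.ndarray] = {}
    for i, rec in enumerate(records):
        crop, result = roi_mod.extract_roi(rec.pixels, chrom=chromosome)
        if use_cheatsheet:
            biopsy = cs.electronic_biopsy(crop, seed=biopsy_seed + i,
                                          enumerate_all=enumerate_biopsy)
            crop = cs.encode_frames(crop, biopsy, result.radius).pixels
        out[rec.id] = resize(crop, target)
    return out


def build_arm(records: Sequence[MammogramRecord], arm: ArmConfig,
              run_seed: int,
              prepared: Optional[Dict[str, np.ndarray]] = None,
              chromosome: Optional[roi_mod.Chromosome] = None) -> dict:
    """Assemble one arm's train/test tensors for one run.

    Returns train/test image stacks with labels, ids, and per-training-image
    provenance (source id, transform) for leakage auditing.
    """
    arm.validate()
    labels = {r.id: (r.label if r.label is not None else label_for(r.class_raw))
              for r in records}
    if prepared is None:
        prepared = prepare_images(records, arm.use_cheatsheet,
                                  chromosome=chromosome)
    train_ids, test_ids = make_split([r.id for r in records],
                                     arm.n_train, arm.n_test, run_seed)
    tr_imgs = [prepared[i] for i in train_ids]
    tr_labels = [labels[i] for i in train_ids]
    if arm.use_augmentation:
        aug = augment_training_set(tr_imgs, tr_labels, ids=train_ids)
        tr_imgs, tr_labels = aug.images(), aug.all_labels()
        provenance = aug.provenance
    else:
        provenance = [(i, "orig") for i in train_ids]
    # leakage audit: nothing derived from a test id may be trained on
    test_set = set(test_ids)
    leaked = [src for src, _ in provenance if src in test_set]
    if leaked:
        raise RuntimeError(f"test images leaked into training: {leaked[:5]}")
    return {"train_x": np.stack(tr_imgs), "train_y": np.array(tr_labels),
            "test_x": np.stack([prepared[i] for i in test_ids]),
            "test_y": np.array([labels[i] for i in test_ids]),
            "train_ids": train_ids, "test_ids": test_ids,
            "provenance": provenance}


def run_experiment(records: Sequence[MammogramRecord],
                   arms: Optional[Sequence[ArmConfig]] = None,
                   n_runs: Optional[int] = None,
                   base_seed: int = 0,
                   model_config: Optional[ModelConfig] = None,
                   chromosome: Optional[roi_mod.Chromosome] = None
                   ) -> pd.DataFrame:
    """Run every arm ``n_runs`` times; one metrics row per arm per run.

    Run ``k`` uses seed ``base_seed + k`` for its split, weight
    initialisation and training shuffles.
    """
    arms = list(arms) if arms is not None else standard_arms(base_seed=base_seed)
    model_config = model_config or ModelConfig()
    # prepare each encoding flavour once; splits/training vary per run
    flavours: Dict[bool, Dict[str, np.ndarray]] = {}
    for a in arms:
        if a.use_cheatsheet not in flavours:
            flavours[a.use_cheatsheet] = prepare_images(
                records, a.use_cheatsheet, chromosome=chromosome,
                biopsy_seed=base_seed)
    rows = []
    for arm in arms:
        runs = n_runs if n_runs is not None else arm.n_runs
        for k in range(runs):
            seed = base_seed + k
            data = build_arm(records, arm, run_seed=seed,
                             prepared=flavours[arm.use_cheatsheet])
            net = build_model(replace(model_config, seed=seed))
            trained = train(net, data["train_x"], data["train_y"],
                            val_fraction=arm.val_fraction, seed=seed)
            scores = trained.predict_proba(data["test_x"])
            m = run_metrics(data["test_y"], scores)
            rows.append({"arm": arm.name, "run": k + 1, "AC": m.AC,
                         "SE": m.SE, "SP": m.SP, "AUOC": m.AUOC})
    return pd.DataFrame(rows)


def save_results(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
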