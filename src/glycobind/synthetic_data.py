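"""Synthetic glycoconjugate structures and binding data.

Every stage of the pipeline — featurization, RFU calibration, model
training, stereo extrapolation — is exercised against data generated here,
with known ground truth and full reproducibility from a seed.

Structures come from a small grammar of pyranose-like rings (randomized
ring stereocenters, hydroxyl/acetamido/deoxy decorations) attached through
an alkyl or glycolyl linker ending in the carboxylic acid used for array
immobilization.  This guarantees chemical validity and a stereocenter
density comparable to real glycans, which random SMILES would not.

Binding truth is rule-based: each synthetic lectin recognizes a
substructure motif (optionally chirality-sensitive, matching glycan
recognition) and assigns a dissociation constant ``kd_hit`` to carriers
and ``kd_miss`` (effectively non-binding) to everything else.  True
fractions bound follow the single-site occupancy curve.  Arrays are then
simulated per (lectin, concentration): six replicate spots per
glycoconjugate whose net RFU is a log-normal background draw plus the
bound fraction of the dynamic range, with multiplicative replicate noise,
clipped at the scanner maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from glycobind.fraction_bound import (
    GLOBAL_MAX_RFU,
    AffinityRecord,
    ConcentrationGrid,
    affinity_to_fraction,
)

_STEREO = ["@", "@@"]
_DECORATIONS = ["O", "NC(C)=O", None]  # hydroxyl, acetamido, deoxy (no substituent)
_DECORATION_P = [0.6, 0.25, 0.15]
_LINKERS = ["OCC(=O)O", "OCCC(=O)O", "OCCCCC(=O)O", "OCCOCC(=O)O"]


@dataclass
class SyntheticRule:
    """One synthetic lectin's specificity: a motif and two affinities.

    ``motif`` is a SMILES substructure query; when ``chirality_sensitive``
    is on, matching honors tetrahedral configuration, so a carrier's
    enantiomer falls back to ``kd_miss`` unless it independently carries
    the motif.
    """

    motif: str
    chirality_sensitive: bool
    kd_hit: float
    kd_miss: float
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.kd_hit >= self.kd_miss:
            raise ValueError("kd_hit must be smaller (stronger) than kd_miss")
        self._query = Chem.MolFromSmiles(self.motif)
        if self._query is None:
            self._query = Chem.MolFromSmarts(self.motif)
        if self._query is None:
            raise ValueError(f"unparseable motif: {self.motif!r}")

    def kd_for(self, mol: Chem.Mol) -> float:
        hit = mol.HasSubstructMatch(self._query, useChirality=self.chirality_sensitive)
        return self.kd_hit if hit else self.kd_miss


@dataclass
class SimulationConfig:
    """Noise and scale parameters of the simulated arrays.

    ``background_mode`` is the RFU around which non-binder net signals
    cluster (log-normal, spread in log10 decades); ``replicate_noise`` is
    the multiplicative spot-to-spot standard deviation.
    """

    seed: int
    n_molecules: int = 200
    n_lectins: int = 5
    concentrations: ConcentrationGrid = field(
        default_factory=lambda: ConcentrationGrid(values=np.array([0.1, 1.0, 10.0, 100.0]), unit="uM")
    )
    background_mode: float = 150.0
    background_spread: float = 0.2
    replicate_noise: float = 0.1
    n_replicates: int = 6
    global_max: float = GLOBAL_MAX_RFU
    scanner_offset: float = 30.0

    def __post_init__(self) -> None:
        if min(self.background_spread, self.replicate_noise) < 0:
            raise ValueError("noise parameters must be ≥ 0")


def default_rules(n_lectins: int = 5) -> dict[str, SyntheticRule]:
    """Motif rules for up to six synthetic lectins.

    Most are chirality-sensitive: single ring-configuration motifs (the way
    real lectins distinguish epimeric sugars such as Gal vs Glc) and
    two-center motifs; one recognizes the acetamido decoration regardless
    of configuration, providing an achiral control.  Hit affinities sit at
    0.2–0.5 μM so the weakest dose on the default grid (0.1 μM) already
    produces a signal far above the background-peak search window, while
    ``kd_miss`` = 1 M leaves non-binders indistinguishable from background
    at every dose.
    """
    catalog = [
        SyntheticRule("OC[C@H]1OCCCC1", True, 0.5, 1e6),
        SyntheticRule("CO[C@@H]1OCCCC1", True, 0.3, 1e6),
        SyntheticRule("OC[C@@H]1O[C@H](OC)CCC1", True, 0.5, 1e6),
        SyntheticRule("OCC1OC(OC)C(NC(C)=O)CC1", False, 0.4, 1e6),
        SyntheticRule("CO[C@H]1OCC[C@@H](O)C1", True, 0.2, 1e6),
        SyntheticRule("OC[C@@H]1O[C@@H](OC)CCC1", True, 0.5, 1e6),
    ]
    if not 1 <= n_lectins <= len(catalog):
        raise ValueError(f"n_lectins must be in [1, {len(catalog)}]")
    return {f"L{i}": catalog[i] for i in range(n_lectins)}


def _random_pyranoside(rng: np.random.Generator) -> str:
    """One pyranose-like ring with random stereo tags and decorations."""
    tags = [rng.choice(_STEREO) for _ in range(5)]
    linker = _LINKERS[rng.integers(len(_LINKERS))]
    ring_subs = []
    for _ in range(3):
        d = _DECORATIONS[rng.choice(len(_DECORATIONS), p=_DECORATION_P)]
        ring_subs.append(d)
    parts = [f"OC[C{tags[0]}H]1O[C{tags[1]}H]({linker})"]
    for tag, sub in zip(tags[2:4], ring_subs[:2]):
        parts.append(f"[C{tag}H]({sub})" if sub else "C")
    parts.append(f"[C{tags[4]}H]1{ring_subs[2]}" if ring_subs[2] else "C1")
    return "".join(parts)


def generate_glycans(
    n: int,
    seed: int,
    include_enantiomer_pairs: bool = False,
    pair_fraction: float = 0.3,
) -> pd.DataFrame:
    """Deterministic table of valid, stereocenter-rich glycoconjugate SMILES.

    Returns columns ``record_id``, ``smiles``, ``base_id``.  When
    ``include_enantiomer_pairs`` is set, ``pair_fraction`` of the molecules
    form exact mirror-image pairs; pair members share a ``base_id`` so that
    grouped cross-validation can hold a pair out together.
    """
    if n < 2:
        raise ValueError("need n ≥ 2")
    from glycobind.featurize import parse_molecule
    from glycobind.stereo import enantiomer

    rng = np.random.default_rng(seed)
    n_pairs = int(round(n * pair_fraction / 2)) if include_enantiomer_pairs else 0
    n_base = n - n_pairs  # each pair contributes its parent plus one mirror

    seen: set[str] = set()
    rows = []
    i = 0
    while len(rows) < n_base:
        smiles = _random_pyranoside(rng)
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
        if canonical in seen:
            continue
        seen.add(canonical)
        rid = f"G{i:04d}"
        rows.append({"record_id": rid, "smiles": canonical, "base_id": rid})
        i += 1
    for j in range(n_pairs):
        parent = rows[j]
        ent = enantiomer(parse_molecule(parent["smiles"]), parent_id=parent["record_id"])
        rows.append(
            {
                "record_id": f"{parent['record_id']}_ent",
                "smiles": ent.variant_graph.canonical_smiles(),
                "base_id": parent["base_id"],
            }
        )
    return pd.DataFrame(rows)


def assign_true_affinities(
    structures: pd.DataFrame,
    rules: dict[str, SyntheticRule],
    grid: ConcentrationGrid,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Ground-truth Kd table and f-surface from motif matching.

    Returns an affinity table (molecule_id, lectin_group_id, value, kind,
    unit) and the true fraction-bound tensor of shape
    (n_molecules, n_concentrations, n_lectins) from the occupancy curve.
    """
    if not rules:
        raise ValueError("no rules given")
    lectin_ids = sorted(rules)
    mols = [Chem.MolFromSmiles(s) for s in structures["smiles"]]
    if any(m is None for m in mols):
        raise ValueError("unparseable structure in table")
    records = []
    true_f = np.zeros((len(mols), len(grid), len(lectin_ids)))
    for li, lectin in enumerate(lectin_ids):
        rule = rules[lectin]
        for mi, (mol, mid) in enumerate(zip(mols, structures["record_id"])):
            kd = rule.kd_for(mol)
            records.append(
                {"molecule_id": mid, "lectin_group_id": lectin, "value": kd, "kind": "Kd", "unit": rule.unit}
            )
            aff = AffinityRecord(mid, lectin, kd, "Kd", rule.unit)
            for ci, c in enumerate(grid.values):
                true_f[mi, ci, li] = affinity_to_fraction(aff, float(c), unit=grid.unit)
    return pd.DataFrame(records), true_f


def simulate_array(
    true_f_surface: np.ndarray,
    cfg: SimulationConfig,
    molecule_ids: list[str],
    lectin_ids: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spot tables and metadata for every (lectin, concentration).

    Per spot: net RFU = log-normal background draw around
    ``background_mode`` + f · (global_max − background_mode), with
    multiplicative replicate noise, clipped at ``global_max``.  Foreground
    adds a constant scanner offset that the background column reports, so
    foreground − background recovers the net signal.
    """
    n_mol, n_conc, n_lec = true_f_surface.shape
    if n_mol != len(molecule_ids) or n_lec != len(lectin_ids) or n_conc != len(cfg.concentrations):
        raise ValueError("surface shape does not match ids/config")
    rng = np.random.default_rng(cfg.seed)
    spot_rows, meta_rows = [], []
    dynamic_range = cfg.global_max - cfg.background_mode
    for li, lectin in enumerate(lectin_ids):
        for ci, conc in enumerate(cfg.concentrations.values):
            array_id = f"{lectin}_a{ci}"
            meta_rows.append(
                {
                    "array_id": array_id,
                    "cbpID": lectin,
                    "sample_description": "synthetic lectin prep",
                    "investigator": "simulator",
                    "concentration": float(conc),
                    "unit": cfg.concentrations.unit,
                }
            )
            for mi, mid in enumerate(molecule_ids):
                f = true_f_surface[mi, ci, li]
                bg_draw = cfg.background_mode * 10 ** rng.normal(0.0, cfg.background_spread)
                net = bg_draw + f * dynamic_range
                for rep in range(1, cfg.n_replicates + 1):
                    noisy = net * (1.0 + rng.normal(0.0, cfg.replicate_noise))
                    noisy = float(np.clip(noisy, 0.0, cfg.global_max))
                    spot_rows.append(
                        {
                            "array_id": array_id,
                            "glycoconjugate_id": mid,
                            "replicate": rep,
                            "foreground": noisy + cfg.scanner_offset,
                            "background": cfg.scanner_offset,
                        }
                    )
    return pd.DataFrame(spot_rows), pd.DataFrame(meta_rows)
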