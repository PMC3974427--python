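"""Loaders for the packaged reference dataset of the Peninsular Malaysian
*Plectostoma* revision: the 32-row shell-character matrix with its state
legend, the 30-couplet identification key, the 19-species COI divergence
table, the 51 barcoded collection records, and the per-species shell
descriptions."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .barcode import GroupDivergenceTable, read_distance_table
from .morphology import (
    CharacterDefinition,
    CharacterMatrix,
    SpeciesDescription,
    load_matrix,
)
from .records_geo import CollectionRecord, load_records
from .taxo_key import DichotomousKey, load_key

_DATA = resources.files("plectokit") / "data"

N_GENERAL_CHARACTERS = 11


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def character_definitions() -> tuple[CharacterDefinition, ...]:
    """The legend of the 11 general qualitative shell characters."""
    with (_DATA / "characters.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    defs = tuple(
        CharacterDefinition(
            character_id=c["character_id"],
            name=c["name"],
            state_codes={int(k): v for k, v in c["state_codes"].items()},
            figure_ref=c.get("figure_ref", ""),
        )
        for c in raw["characters"]
    )
    if len(defs) != N_GENERAL_CHARACTERS:
        raise ValueError(
            f"expected {N_GENERAL_CHARACTERS} characters, got {len(defs)}"
        )
    return defs


def character_matrix() -> CharacterMatrix:
    """The 32-row x 11-character state matrix (two rows are P. ikanensis forms)."""
    return load_matrix(_data_path("table3_matrix.tsv"), character_definitions())


def identification_key() -> DichotomousKey:
    """The 30-couplet dichotomous key with curated machine predicates."""
    return load_key(_data_path("key31.yaml"))


def divergence_table() -> GroupDivergenceTable:
    """Within-species and net between-species COI K2P divergences (19 species)."""
    return read_distance_table(_data_path("table4_divergences.tsv"))


def collection_records() -> list[CollectionRecord]:
    """The 51 barcoded collection records with hill-centroid coordinates."""
    return load_records(_data_path("table2_records.tsv"))


def species_descriptions() -> dict[str, SpeciesDescription]:
    """Quantitative shell-description records for all 31 revised species."""
    with (_DATA / "descriptions.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    known = {
        "spire_height",
        "spire_width",
        "whorls",
        "rib_density",
        "whorl_periphery",
        "tuba_length_ratio",
        "tuba_attachment",
        "type_locality",
    }
    out: dict[str, SpeciesDescription] = {}
    for sp, fields in raw["species"].items():
        extras = {k: v for k, v in fields.items() if k not in known}
        out[sp] = SpeciesDescription(
            species=sp,
            spire_height=tuple(fields["spire_height"]),
            spire_width=tuple(fields["spire_width"]),
            whorls=tuple(fields["whorls"]),
            rib_density=tuple(fields["rib_density"]),
            whorl_periphery=frozenset(fields.get("whorl_periphery", [])),
            tuba_length_ratio=(
                tuple(fields["tuba_length_ratio"])
                if "tuba_length_ratio" in fields
                else None
            ),
            tuba_attachment=(
                tuple(fields["tuba_attachment"])
                if "tuba_attachment" in fields
                else None
            ),
            type_locality=(
                tuple(fields["type_locality"]) if "type_locality" in fields else None
            ),
            extras=extras,
        )
    return out
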