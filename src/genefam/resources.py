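"""Packaged data resources.

Physicochemical constant tables (hydropathy, dipeptide instability weights,
pKa set, residue masses), the consensus cis-element catalog, and the bundled
Hsf-family reference tables (per-protein profile columns and paralog-pair
divergence values transcribed from the published family survey). All tables
are plain JSON/TSV so they can be inspected or swapped.
"""
from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources as _ir

import pandas as pd

def _read_text(name: str) -> str:
    return _ir.files("genefam").joinpath("data", name).read_text()


@lru_cache(maxsize=None)
def hydropathy_table() -> dict[str, float]:
    """Kyte-Doolittle (1982) per-residue hydropathy values."""
    return json.loads(_read_text("hydropathy_kyte_doolittle.json"))["values"]


@lru_cache(maxsize=None)
def diwv_table() -> dict[str, dict[str, float]]:
    """Guruprasad et al. (1990) dipeptide instability weight values."""
    return json.loads(_read_text("instability_diwv.json"))["values"]


@lru_cache(maxsize=None)
def pka_set() -> dict:
    """EMBOSS-style pKa set for the ionizable residues and termini."""
    return json.loads(_read_text("pka_emboss.json"))


@lru_cache(maxsize=None)
def residue_masses() -> dict:
    """Average residue masses (Da) and the water mass added per chain."""
    return json.loads(_read_text("residue_masses.json"))


@lru_cache(maxsize=None)
def default_catalog_json() -> dict:
    """Raw JSON of the packaged consensus cis-element catalog."""
    return json.loads(_read_text("cis_element_catalog.json"))


def hsf_family_profile() -> pd.DataFrame:
    """Bundled Hsf family profile: class, length, charged-residue counts."""
    with _ir.files("genefam").joinpath("data", "hsf_family_profile.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def hsf_paralog_pairs() -> pd.DataFrame:
    """Bundled Hsf paralog pairs: duplication type, Ka, Ks, Ka/Ks, date."""
    with _ir.files("genefam").joinpath("data", "hsf_paralog_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
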