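"""Package-wide defaults and structured-config loading.

Every tunable the detectors use lives here so that a survey run can be
reproduced from one YAML file: motif definitions, reference provenance,
detection windows, attC length bounds and fold-acceptance thresholds, the
canonical extrahelical-base (EHB) specification, and assay-statistics
options. ``load_config(path)`` merges a YAML mapping over the defaults.
"""

from __future__ import annotations

import copy
import logging

logger = logging.getLogger("integronkit")

DEFAULT_CONFIG: dict = {
    # Consensus motifs (IUPAC strings) used by the detectors.
    "motifs": {
        "core_site": "GTTRRRY",
        "inverse_core_site": "RYYYAAC",
        "delta_attI1": "AAACAAAGTTRRRY",
        "delta_attI2": "AATAAAATGTTRRRY",
        "L_box": "CCCTAAA",
    },
    # Provenance of the bundled synthetic reference attI sites.
    "references": {
        "attI1": {"modelled_on": "NC_028464", "length": 65, "crossover_g_index": 56},
        "attI2": {"modelled_on": "DQ176450", "length": 311, "crossover_g_index": 305},
    },
    "delta_atti": {
        # A consensus match is accepted as a cassette-borne site only when it
        # starts within this many nt downstream of an ORF stop codon.
        "orf_context_window": 150,
        # Upstream extension requires exact identity to the reference by
        # default; a small mismatch budget can be enabled for exploration.
        "max_extension_mismatches": 0,
    },
    "attc": {
        "min_length": 57,
        "max_length": 141,
        # Minimal unpaired central loop assumed when slicing candidate arms.
        "min_loop": 10,
        "gap_penalty": 1,
        "wobble_pairs": False,
        # A candidate core pair is accepted as an attC site when the fraction
        # of arm positions Watson-Crick paired by the fold reaches this value
        # (true sites are near-perfect inverted repeats; spurious core pairs
        # align random arms and score far lower).
        "min_paired_fraction": 0.75,
        # Canonical EHB specification (literature-derived default, not a
        # value printed by the survey this package models; override freely).
        "canonical_ehbs": [
            {"base": "G", "stem_offset": 13},
            {"base": "T", "stem_offset": 19},
        ],
        "ehb_position_tolerance": 1,
    },
    "arrays": {
        "tandem_identity_threshold": 1.0,
        "tandem_key": "full_cassette",
        # An ORF whose downstream site is missing but which ends within this
        # many nt of the contig edge is emitted as a "-truncated" cassette.
        "edge_window": 150,
    },
    "assay": {
        "alpha": 0.05,
        "multiple_testing": None,  # or "holm"
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge(base: dict, override: dict) -> dict:
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _merge(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path=None) -> dict:
    """Return the default config, optionally overlaid with a YAML file."""
    cfg = default_config()
    if path is not None:
        import yaml

        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError("config file must contain a mapping")
        _merge(cfg, override)
    return cfg
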