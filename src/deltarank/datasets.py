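"""Access to the small bundled fixture data.

The bundled network is a synthetic stand-in: a few hundred edges over
invented gene symbols, enough to exercise the pipeline end to end. Real
analyses should supply a pathway-derived background network as an edge
list.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import read_network
from .network import BackgroundNetwork, clean_network


def fixture_network_path() -> Path:
    """Path to the bundled synthetic fixture network (TSV edge list)."""
    return Path(resources.files("deltarank") / "data" / "fixture_network.tsv")


def load_fixture_network() -> BackgroundNetwork:
    return clean_network(read_network(fixture_network_path()))
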