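"""Static reference tables: published biological mutation rates, genetic
distances between alleles, and A. thaliana crossover rates.

These are data, not computation: they annotate plots and reports (e.g.
the per-base per-generation rate bands drawn alongside simulated CMRs)
and never feed the simulator.  Files are plain CSV under ``data/`` and
are validated against embedded checksums at load time.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

_CHECKSUMS = {
    "bio_rates": "090d020522d301628a5e4a6bfbf668e7d03632f4b5cecf900a65467361acea79",
    "allele_distances": "70e16a2920c43bae36379fcd6b844e3ccd8ec89040eab12dbbf0e4fc42a21593",
    "crossover_rates": "486088cd877b860034a98ffb976f3ffa33d4f7168dbd15638c26b9609351155d",
}


class FixtureIntegrityError(RuntimeError):
    """A bundled fixture file does not match its recorded checksum."""


def fixture_names():
    return sorted(_CHECKSUMS)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled reference table by name.

    Known names: ``bio_rates`` (species mutation rates; columns species,
    genome_size_mbp, rate_low, rate_high, basis, unit), ``allele_distances``
    (gene, distance, unit, note) and ``crossover_rates`` (A. thaliana
    male/female crossover counts).  Unknown names raise ``KeyError``.
    """
    if name not in _CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    ref = resources.files("cmrsim").joinpath("data", f"{name}.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"fixture {name!r} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))
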