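"""Reference tables shipped with the package.

Published summary statistics of two whole-genome-resequencing F2 bin
maps in melon — WAP (cultivated *agrestis* x wild *agrestis*) and MAP
(cultivated *melo* x cultivated *agrestis*), 200 individuals each over
12 chromosomes.  Used to re-tabulate map-level summaries (totals,
events per individual, mean bin size) through the same reporting code
that serves freshly computed maps.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_chromosome_stats", "load_population_stats"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_chromosome_stats() -> pd.DataFrame:
    """Per-chromosome bin counts and genetic lengths (cM) per population."""
    return _read("melon_f2_chromosome_stats.csv")


def load_population_stats() -> pd.DataFrame:
    """Population-level totals: individuals, recombination events, covered Mb, bins."""
    return _read("melon_f2_population_stats.csv")
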