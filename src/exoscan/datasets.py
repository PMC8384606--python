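"""Small bundled input datasets and worked-example fixtures.

``ELITE_EXOTIC_SNP_COUNTS`` is the published table of mean de novo SNP calls
per chromosome for the elite and exotic subpopulations of a 149-line spring
wheat diversity panel (the study this package's methods reproduce); feeding
it through :func:`exoscan.diversity.density_contrast` regenerates the printed
percentage differences, e.g. +62.02% for the whole D subgenome and +202.24%
on chromosome 3D.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, HOM_REF, HET, HOM_ALT, MISSING

# unit -> (elite mean count, exotic mean count)
ELITE_EXOTIC_SNP_COUNTS: dict[str, tuple[int, int]] = {
    "chr1A": (45734, 47865),
    "chr1B": (49306, 55034),
    "chr1D": (9372, 9423),
    "chr2A": (46243, 53899),
    "chr2B": (60874, 62237),
    "chr2D": (9284, 12458),
    "chr3A": (33536, 35550),
    "chr3B": (97429, 97734),
    "chr3D": (7892, 23853),
    "chr4A": (35341, 34540),
    "chr4B": (12840, 30796),
    "chr4D": (3597, 4099),
    "chr5A": (36687, 38698),
    "chr5B": (56866, 57567),
    "chr5D": (5850, 8960),
    "chr6A": (40510, 41888),
    "chr6B": (63171, 65299),
    "chr6D": (5684, 8218),
    "chr7A": (53058, 54033),
    "chr7B": (44757, 55862),
    "chr7D": (7872, 13268),
    "A_genome": (291110, 306473),
    "B_genome": (385242, 424530),
    "D_genome": (49550, 80280),
}


def elite_exotic_counts() -> pd.DataFrame:
    rows = [(u, e, x) for u, (e, x) in ELITE_EXOTIC_SNP_COUNTS.items()]
    return pd.DataFrame(rows, columns=["unit", "elite_mean", "exotic_mean"])


def ten_locus_filter_fixture() -> tuple[GenotypeMatrix, list[int]]:
    """Hand-built 20-sample, 10-locus matrix with an enumerated survivor set.

    Under the standard locus filter (<10% missing data, MAF >= 5%) exactly
    loci 0, 2, 4, 6 and 9 survive:

    ====  ========  ================  ====================  ========
    locus missing   alt carriers      MAF                   keeps?
    ====  ========  ================  ====================  ========
    0     0/20      10 HOM_ALT        0.50                  yes
    1     3/20      8 HOM_ALT         (15% missing)         no
    2     0/20      1 HOM_ALT         0.05 (boundary)       yes
    3     0/20      0                 0.00 monomorphic      no
    4     1/20      2 HOM_ALT         2/19 = 0.105          yes
    5     2/20      9 HOM_ALT         (10% missing, not <)  no
    6     0/20      19 HOM_ALT        minor = 0.05          yes
    7     0/20      20 HOM_ALT        monomorphic alt       no
    8     1/20      0                 0.00                  no
    9     0/20      9 HOM_ALT + 2 HET (18+2)/40 = 0.50      yes
    ====  ========  ================  ====================  ========
    """
    n = 20
    samples = [f"s{i:02d}" for i in range(n)]

    def row(n_missing=0, n_alt=0, n_het=0):
        calls = np.full(n, HOM_REF, dtype=np.int8)
        calls[:n_alt] = HOM_ALT
        calls[n_alt:n_alt + n_het] = HET
        if n_missing:
            calls[-n_missing:] = MISSING
        return calls

    spec = [
        dict(n_alt=10),
        dict(n_alt=8, n_missing=3),
        dict(n_alt=1),
        dict(),
        dict(n_alt=2, n_missing=1),
        dict(n_alt=9, n_missing=2),
        dict(n_alt=19),
        dict(n_alt=20),
        dict(n_missing=1),
        dict(n_alt=9, n_het=2),
    ]
    calls = np.vstack([row(**s) for s in spec])
    loci = pd.DataFrame(
        {
            "chrom": "chr1A",
            "pos": np.arange(1, len(spec) + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    matrix = GenotypeMatrix(loci=loci, samples=samples, calls=calls)
    survivors = [0, 2, 4, 6, 9]
    return matrix, survivors
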