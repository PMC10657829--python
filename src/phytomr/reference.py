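"""Published summary tables used as reference inputs.

Frequency columns of the published prescription-corpus tables for
compensated and decompensated hepatitis B cirrhosis (herbs used more than
20 / more than 40 times respectively), plus the published corpus-level and
attribute-axis aggregate counts.  These printed counts are inputs: the
package's statistics are recomputed from corpora reconstructed to match
them.
"""

from __future__ import annotations

# herbs used >20 times in the compensated corpus (98 prescriptions)
COMPENSATED_FREQUENCIES: dict[str, int] = {
    "Paeoniae Radix Alba": 58,
    "Salviae Miltiorrhizae Radix Et Rhizoma": 54,
    "Bupleuri Radix": 54,
    "Trionycis Carapax": 53,
    "Atrctylodis Macrocephalae Rhizoma": 53,
    "Poria": 49,
    "Astragali Radix": 43,
    "Angelicae Sinensis Radix": 40,
    "Glycyrrhizae Radix Et Rhizoma": 37,
    "Persicae Semen": 25,
    "Paeoniae Radix Rubra": 23,
    "Curcumae Radix": 22,
}
COMPENSATED_N_PRESCRIPTIONS = 98

# decompensated corpus aggregates (241 prescriptions, 204 distinct herbs)
DECOMPENSATED_N_PRESCRIPTIONS = 241
DECOMPENSATED_TOTAL_OCCURRENCES = 2958
DECOMPENSATED_TOP_HERB = "Poria"
DECOMPENSATED_TOP_HERB_FREQUENCY = 173
DECOMPENSATED_TOP20_OCCURRENCES = 1702

# attribute-axis aggregates (occurrence-weighted counts)
COMPENSATED_PROPERTY_TOTAL = 803
COMPENSATED_PROPERTY_COLD = 381
COMPENSATED_MERIDIAN_TOTAL = 1987
COMPENSATED_MERIDIAN_LIVER = 507
DECOMPENSATED_FLAVOR_TOTAL = 3377
DECOMPENSATED_FLAVOR_SWEET = 1286
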