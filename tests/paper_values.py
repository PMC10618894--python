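"""Published summary values used as test inputs and expectations.

Site rows: (site, period, N, MLG, GD, GD_Shannon, GD_Simpson) as printed in
the source study's diversity table. The TPT row's printed GD (0.34) is
internally inconsistent with its printed N/MLG ((13-1)/(30-1) = 0.41), so it
is excluded from formula-consistency checks but retained where the printed
column itself is the input.
"""

SITE_ROWS = [
    ("NBB",   "pre",  20, 11, 0.53, 0.44, 0.37),
    ("BNR",   "pre",  30, 12, 0.38, 0.20, 0.10),
    ("GAR",   "pre",  27,  8, 0.27, 0.11, 0.05),
    ("IONA",  "pre",  29, 17, 0.57, 0.48, 0.40),
    ("CRO11", "pre",  29, 27, 0.93, 0.89, 0.82),
    ("WPT",   "post",  2,  2, 1.00, 1.00, 1.00),
    ("ANT",   "post", 33, 16, 0.47, 0.30, 0.19),
    ("ACR",   "post", 30, 24, 0.79, 0.74, 0.67),
    ("TPT",   "post", 30, 13, 0.34, 0.19, 0.09),
    ("GIS",   "post", 30,  7, 0.21, 0.11, 0.08),
    ("STP",   "post", 31, 18, 0.57, 0.40, 0.27),
    ("CPN",   "post", 23,  6, 0.23, 0.11, 0.06),
    ("CRO15", "post", 30, 22, 0.72, 0.61, 0.48),
    ("NYK",   "post", 30,  5, 0.14, 0.03, 0.01),
]

GD_INCONSISTENT = {"TPT"}  # printed GD does not match printed N/MLG

# overall (G, N, printed GD): pre-storm, post-storm, both periods combined
OVERALL = {"pre": (73, 135, 0.54), "post": (110, 239, 0.46),
           "combined": (178, 374, 0.47)}

# printed column means over sites (WPT excluded from the post mean)
MEAN_GD = {"pre": 0.54, "post": 0.43}

# multi-shoot MLGs before the storms: 22 of 73 (30.1%)
MULTI_SHOOT = (22, 73, 30.1)

# MLG counts: 73 pre + 110 post with 5 shared -> 178 total
MLG_UNION = (73, 110, 5, 178)

# permutation p-values for pre vs post site-level effective GD columns
PERM_P = {"GD_shannon": 0.49, "GD_simpson": 0.46}
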