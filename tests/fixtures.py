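"""Constructed gene fixtures spanning the screen's filter thresholds."""

from khscan import CodonAlignment


def _gene(gid, cols):
    return CodonAlignment(gid, "".join(c[0] for c in cols), "".join(c[1] for c in cols))


def six_gene_fixture():
    """Six hand-built genes, one per screening outcome (fixed kappa = 2).

    g_ka_high: 30 Lys->Arg changes push Ka ~ 0.07 over the 0.05 cap.
    g_ks_high: 16 fourfold synonymous changes push Ks ~ 0.085 over 0.08.
    g_ks_low:  identical sequences, Ks = 0 below the 0.005 floor.
    g_psg:     10 Ile->Leu (top-ranked class) changes against Ks ~ 0.02,
               K_h/K_s ~ 7.5 with exact-test p ~ 1e-4: candidate PSG.
    g_weak:    2 Ile->Leu changes, K_h/K_s > 1 but p ~ 0.64: not a PSG.
    g_null:    mixed background, unfiltered, not a PSG.
    """
    return [
        _gene("g_ka_high", [("AAA", "AGA")] * 30 + [("GGA", "GGG")] * 2
              + [("AAA", "AAA")] * 168),
        _gene("g_ks_high", [("GGA", "GGG")] * 16 + [("GGC", "GGC")] * 184),
        _gene("g_ks_low", [("AAA", "AAA")] * 200),
        _gene("g_psg", [("ATA", "TTA")] * 10 + [("ATT", "ATT")] * 80
              + [("GGA", "GGG")] * 8 + [("GGC", "GGC")] * 302),
        _gene("g_weak", [("ATA", "TTA")] * 2 + [("ATT", "ATT")] * 80
              + [("GGA", "GGG")] * 6 + [("GGC", "GGC")] * 212),
        _gene("g_null", [("GGA", "GGG")] * 4 + [("AAA", "AGA")] * 1
              + [("AAA", "AAA")] * 60 + [("GGC", "GGC")] * 135),
    ]


EXPECTED_FLAGS = {
    "g_ka_high": (True, "ka_gt_max", False),
    "g_ks_high": (True, "ks_gt_max", False),
    "g_ks_low": (True, "ks_lt_min", False),
    "g_psg": (False, None, True),
    "g_weak": (False, None, False),
    "g_null": (False, None, False),
}
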