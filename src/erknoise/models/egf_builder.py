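"""Programmatic construction of the EGF-ERK-NPC signalling network.

The network is a calibrated reconstruction of a mammalian EGF signalling
pathway with autoregulatory control of ERK nuclear translocation:

* receptor layer — EGF binding, receptor dimerization, trans-autophosphorylation,
  receptor phosphatase, internalization/recycling/degradation;
* adaptor layer — Shc-dependent and Shc-independent recruitment of Grb2-Sos
  to the phosphorylated receptor;
* Ras layer — Sos-complex-mediated GDP/GTP exchange, GAP-mediated and
  intrinsic hydrolysis;
* Raf layer — Ras-state-dependent Raf binding with an intermediate activation
  step (only RasGTP-bound Raf activates), Raf phosphatase;
* MEK/ERK layer — distributive two-step (de)phosphorylation cycles with
  explicit enzyme-substrate complexes, separate cytoplasmic and nuclear ERK
  phosphatase pools, and ERK-to-Sos negative feedback;
* nuclear pore layer — ERK shuttles through the NPC via explicit transport
  complexes; nuclear ppERK phosphorylates the pore in two steps (NPC -> pNPC
  -> ppNPC, reactions 137-144); doubly phosphorylated pore translocates ERK
  unidirectionally from nucleus to cytoplasm, closing a negative feedback on
  nuclear ERK accumulation that sharpens the nuclear ERK dose response.

State unit is molecule count.  Bimolecular rate constants are stored
volume-scaled (per molecule per second).  EGF is a clamped (buffered) species:
the extracellular dose is held constant.

The network is synthetic in the sense that its rate constants were calibrated
against published dose-response characteristics of this pathway (Hill
coefficients, EC10/EC90 window, basal fluctuation size) rather than measured
individually; see docs/methods.md.
"""

from __future__ import annotations

from ..network import ReactionNetwork, Reaction, Species

#: clamped EGF molecule count per (ng/mL) of extracellular dose
#: (6.045 kDa ligand, 1 ng/mL = 0.1654 nM, referred to a 1 pL volume)
EGF_MOLECULES_PER_NG_ML = 99.6

#: compartment volumes (litres); nuclear/cytoplasmic ratio typical of a
#: ~1 pL mammalian cell
VOLUMES = {"membrane": 1.0e-13, "cytoplasm": 1.0e-12, "nucleus": 2.2e-13}

# ---------------------------------------------------------------------------
# species: (id, compartment, initial molecule count)
# ---------------------------------------------------------------------------

SPECIES: list[tuple[str, str, int]] = [
    ("EGF", "membrane", 0),                 # clamped; set by the dose
    ("EGFR", "membrane", 90_000),
    ("Ra", "membrane", 0),                  # EGF-EGFR
    ("R2", "membrane", 0),                  # (EGF-EGFR)2
    ("RP", "membrane", 0),                  # autophosphorylated dimer
    ("RPase", "membrane", 5_000),
    ("RPase_RP", "membrane", 0),
    ("Ri", "membrane", 0),                  # internalized receptor dimer
    ("Rd", "membrane", 0),                  # degraded receptor (sink, dimer units)
    ("Shc", "cytoplasm", 100_000),
    ("R_Sh", "membrane", 0),
    ("R_ShP", "membrane", 0),
    ("ShP", "cytoplasm", 0),
    ("Grb2", "cytoplasm", 60_000),
    ("R_ShG", "membrane", 0),
    ("Sh_G", "cytoplasm", 0),
    ("Sos", "cytoplasm", 20_000),
    ("R_ShGS", "membrane", 0),
    ("Sh_GS", "cytoplasm", 0),
    ("R_G", "membrane", 0),
    ("R_GS", "membrane", 0),
    ("G_S", "cytoplasm", 0),
    ("RasGDP", "membrane", 60_000),
    ("RasGTP", "membrane", 0),
    ("R_ShGS_Ras", "membrane", 0),
    ("R_GS_Ras", "membrane", 0),
    ("GAP", "membrane", 12_000),
    ("GAP_RasGTP", "membrane", 0),
    ("Raf", "cytoplasm", 20_000),
    ("RasGDP_Raf", "membrane", 0),
    ("RasGTP_Raf", "membrane", 0),
    ("RasGTP_Raf_a", "membrane", 0),        # activation intermediate
    ("aRaf", "cytoplasm", 0),               # activated Raf
    ("RafPase", "cytoplasm", 4_000),
    ("RafPase_aRaf", "cytoplasm", 0),
    ("MEK", "cytoplasm", 400_000),
    ("pMEK", "cytoplasm", 0),
    ("ppMEK", "cytoplasm", 0),
    ("aRaf_MEK", "cytoplasm", 0),
    ("aRaf_pMEK", "cytoplasm", 0),
    ("MEKPase", "cytoplasm", 30_000),
    ("MEKPase_pMEK", "cytoplasm", 0),
    ("MEKPase_ppMEK", "cytoplasm", 0),
    ("ERKc", "cytoplasm", 675_000),
    ("pERKc", "cytoplasm", 0),
    ("ppERKc", "cytoplasm", 0),
    ("ppMEK_ERK", "cytoplasm", 0),
    ("ppMEK_pERK", "cytoplasm", 0),
    ("ERKPc", "cytoplasm", 100_000),
    ("ERKPc_pERK", "cytoplasm", 0),
    ("ERKPc_ppERK", "cytoplasm", 0),
    ("ppERK_Sos", "cytoplasm", 0),
    ("pSos", "cytoplasm", 0),
    ("SosPase", "cytoplasm", 5_000),
    ("SosPase_pSos", "cytoplasm", 0),
    ("ERKn", "nucleus", 75_000),
    ("pERKn", "nucleus", 0),
    ("ppERKn", "nucleus", 0),
    ("ERKPn", "nucleus", 30_000),
    ("ERKPn_pERK", "nucleus", 0),
    ("ERKPn_ppERK", "nucleus", 0),
    ("NPC", "nucleus", 3_000),
    ("pNPC", "nucleus", 0),
    ("ppNPC", "nucleus", 0),
    ("ppERKn_NPC", "nucleus", 0),
    ("ppERKn_pNPC", "nucleus", 0),
    ("NPCPase", "nucleus", 300),
    ("NPCPase_pNPC", "nucleus", 0),
    ("NPCPase_ppNPC", "nucleus", 0),
    # ERK-NPC transport complexes (ERK phospho-state x pore phospho-state)
    ("T_ERK_NPC", "nucleus", 0),
    ("T_ERK_pNPC", "nucleus", 0),
    ("T_ERK_ppNPC", "nucleus", 0),
    ("T_pERK_NPC", "nucleus", 0),
    ("T_pERK_pNPC", "nucleus", 0),
    ("T_pERK_ppNPC", "nucleus", 0),
    ("T_ppERK_NPC", "nucleus", 0),
    ("T_ppERK_pNPC", "nucleus", 0),
    ("T_ppERK_ppNPC", "nucleus", 0),
]

# ---------------------------------------------------------------------------
# rate constants (calibrated); unimolecular 1/s, bimolecular 1/(molecule s)
# ---------------------------------------------------------------------------

PARAMS: dict[str, float] = {
    # receptor layer
    "kon_EGF": 3.4e-6, "koff_EGF": 1.0e-3,
    "kdim": 3.0e-5, "koff_dim": 0.1,
    "kphos_R": 2.0,
    "kon_RPase": 1.66e-5, "koff_RPase": 0.5, "kcat_RPase": 2.0,
    "k_int": 5.0e-4, "k_rec": 1.0e-3, "k_deg": 2.0e-4,
    # adaptor layer
    "kon_Shc": 1.0e-6, "koff_Shc": 0.1,
    "kphos_Shc": 3.0, "kdeph_RShP": 0.05,
    "koff_RpShc": 0.3, "kon_RpShc": 1.0e-6,
    "kdeph_ShP": 0.05,
    "kon_Grb_RShP": 1.2e-5, "koff_Grb_RShP": 0.05,
    "kon_Sos_RShG": 3.0e-6, "koff_Sos_RShG": 0.05,
    "koff_ShGS_R": 0.1, "kon_ShGS_R": 1.0e-6,
    "koff_ShGS_split": 0.05, "kon_ShGS_join": 1.0e-6,
    "kon_Grb_ShP": 3.0e-7, "koff_Grb_ShP": 0.1,
    "kon_Sos_ShG": 1.0e-6, "koff_Sos_ShG": 0.05,
    "kon_Grb_RP": 1.2e-5, "koff_Grb_RP": 0.05,
    "kon_Sos_RG": 3.0e-6, "koff_Sos_RG": 0.05,
    "koff_GS_R": 0.05, "kon_GS_R": 1.0e-6,
    "kon_GS": 1.0e-7, "koff_GS": 0.05,
    # Ras layer
    "kon_GEF_Ras": 3.0e-6, "koff_GEF_Ras": 1.0, "kexch_Ras": 4.0,
    "kon_GAP": 1.67e-7, "koff_GAP": 1.0, "kcat_GAP": 1.0,
    "khyd_Ras": 1.0e-2,
    # Raf layer
    "kon_RasGDP_Raf": 2.0e-8, "koff_RasGDP_Raf": 1.0,
    "kon_RasGTP_Raf": 6.0e-6, "koff_RasGTP_Raf": 0.3,
    "kact_Raf": 0.6, "kdeact_Raf": 0.1,
    "krel_aRaf": 0.5, "kon_aRaf_RasGTP": 1.0e-7,
    "kon_RafPase": 3.0e-5, "koff_RafPase": 0.5, "kcat_RafPase": 3.0,
    "khyd_Rafa": 0.05,
    "kbasal_Raf_act": 1.0e-7, "kbasal_Raf_deact": 1.0e-3,
    # MEK layer
    "kon_Raf_MEK": 4.0e-6, "koff_Raf_MEK": 0.3, "kcat_Raf_MEK": 3.0,
    "kon_MEKPase": 1.0e-6, "koff_MEKPase": 0.3, "kcat_MEKPase": 1.0,
    "kbasal_pMEK": 1.0e-4, "kbasal_ppMEK": 1.0e-4,
    # ERK layer (cytoplasm); the second phosphorylation step is faster than
    # the first, so the doubly phosphorylated (quadratic) route dominates
    "kon_MEK_ERK": 3.0e-7, "koff_MEK_ERK": 0.3, "kcat_MEK_ERK": 3.0,
    "kon_MEK_ERK2": 1.4e-5, "koff_MEK_ERK2": 0.3, "kcat_MEK_ERK2": 3.0,
    "kon_ERKPc": 1.8e-6, "koff_ERKPc": 0.3, "kcat_ERKPc": 1.0,
    "kbasal_pERKc": 1.0e-4, "kbasal_ppERKc": 1.0e-4,
    # Sos negative feedback (sets the graded pERK Hill coefficient)
    "kon_ppERK_Sos": 1.55e-7, "koff_ppERK_Sos": 0.1, "kcat_ppERK_Sos": 0.05,
    "kon_SosPase": 1.0e-6, "koff_SosPase": 0.3, "kcat_SosPase": 1.0,
    "kbasal_pSos": 1.0e-3,
    # ERK layer (nucleus)
    "kon_ERKPn": 1.0e-6, "koff_ERKPn": 0.3, "kcat_ERKPn": 1.0,
    "kbasal_pERKn": 1.0e-4,
    # ERK-NPC transport (see _transport_table)
    "t_bindc_ERK": 2.0e-6, "t_bindn_ERK": 1.8e-5,
    "t_reln_ERK": 50.0, "t_relc_ERK": 50.0,
    "t_bindc_pERK": 2.0e-6, "t_bindn_pERK": 3.0e-7,
    "t_reln_pERK": 80.0, "t_relc_pERK": 20.0,
    "t_bindn_ppNPC": 2.0e-5, "t_relc_ppNPC": 50.0,
    # NPC phosphorylation by nuclear ERK (knockout set, reactions 137-144)
    "kon_NPCphos1": 6.0e-6, "koff_NPCphos1": 1.0, "kcat_NPCphos1": 0.5,
    "kon_NPCphos2": 6.0e-6, "koff_NPCphos2": 1.0, "kcat_NPCphos2": 0.5,
    "kdirect_NPCphos1": 1.0e-9, "kdirect_NPCphos2": 1.0e-9,
    # NPC dephosphorylation: a small, saturable (zero-order) pool that sets
    # a sharp engagement threshold for the pore switch
    "kon_NPCPase": 5.0e-3, "koff_NPCPase": 0.5, "kcat_NPCPase": 0.87,
    "kbasal_pNPC": 1.0e-4, "kbasal_ppNPC": 1.0e-4,
}

# (index, reactants, products, rate-constant name, tag); transport reactions
# 96-125 are generated from the table below.
REACTIONS: list[tuple[int, list, list, str, str]] = [
    (1, [("EGF", 1), ("EGFR", 1)], [("Ra", 1)], "kon_EGF", "association"),
    (2, [("Ra", 1)], [("EGF", 1), ("EGFR", 1)], "koff_EGF", "dissociation"),
    (3, [("Ra", 2)], [("R2", 1)], "kdim", "association"),
    (4, [("R2", 1)], [("Ra", 2)], "koff_dim", "dissociation"),
    (5, [("R2", 1)], [("RP", 1)], "kphos_R", "phosphorylation"),
    (6, [("RP", 1), ("RPase", 1)], [("RPase_RP", 1)], "kon_RPase", "association"),
    (7, [("RPase_RP", 1)], [("RP", 1), ("RPase", 1)], "koff_RPase", "dissociation"),
    (8, [("RPase_RP", 1)], [("R2", 1), ("RPase", 1)], "kcat_RPase", "dephosphorylation"),
    (9, [("RP", 1)], [("Ri", 1)], "k_int", "translocation"),
    (10, [("Ri", 1)], [("EGFR", 2)], "k_rec", "translocation"),
    (11, [("Ri", 1)], [("Rd", 1)], "k_deg", "degradation"),
    (12, [("RP", 1), ("Shc", 1)], [("R_Sh", 1)], "kon_Shc", "association"),
    (13, [("R_Sh", 1)], [("RP", 1), ("Shc", 1)], "koff_Shc", "dissociation"),
    (14, [("R_Sh", 1)], [("R_ShP", 1)], "kphos_Shc", "phosphorylation"),
    (15, [("R_ShP", 1)], [("R_Sh", 1)], "kdeph_RShP", "dephosphorylation"),
    (16, [("R_ShP", 1)], [("RP", 1), ("ShP", 1)], "koff_RpShc", "dissociation"),
    (17, [("RP", 1), ("ShP", 1)], [("R_ShP", 1)], "kon_RpShc", "association"),
    (18, [("ShP", 1)], [("Shc", 1)], "kdeph_ShP", "dephosphorylation"),
    (19, [("R_ShP", 1), ("Grb2", 1)], [("R_ShG", 1)], "kon_Grb_RShP", "association"),
    (20, [("R_ShG", 1)], [("R_ShP", 1), ("Grb2", 1)], "koff_Grb_RShP", "dissociation"),
    (21, [("R_ShG", 1), ("Sos", 1)], [("R_ShGS", 1)], "kon_Sos_RShG", "association"),
    (22, [("R_ShGS", 1)], [("R_ShG", 1), ("Sos", 1)], "koff_Sos_RShG", "dissociation"),
    (23, [("R_ShGS", 1)], [("RP", 1), ("Sh_GS", 1)], "koff_ShGS_R", "dissociation"),
    (24, [("RP", 1), ("Sh_GS", 1)], [("R_ShGS", 1)], "kon_ShGS_R", "association"),
    (25, [("Sh_GS", 1)], [("ShP", 1), ("G_S", 1)], "koff_ShGS_split", "dissociation"),
    (26, [("ShP", 1), ("G_S", 1)], [("Sh_GS", 1)], "kon_ShGS_join", "association"),
    (27, [("ShP", 1), ("Grb2", 1)], [("Sh_G", 1)], "kon_Grb_ShP", "association"),
    (28, [("Sh_G", 1)], [("ShP", 1), ("Grb2", 1)], "koff_Grb_ShP", "dissociation"),
    (29, [("Sh_G", 1), ("Sos", 1)], [("Sh_GS", 1)], "kon_Sos_ShG", "association"),
    (30, [("Sh_GS", 1)], [("Sh_G", 1), ("Sos", 1)], "koff_Sos_ShG", "dissociation"),
    (31, [("RP", 1), ("Grb2", 1)], [("R_G", 1)], "kon_Grb_RP", "association"),
    (32, [("R_G", 1)], [("RP", 1), ("Grb2", 1)], "koff_Grb_RP", "dissociation"),
    (33, [("R_G", 1), ("Sos", 1)], [("R_GS", 1)], "kon_Sos_RG", "association"),
    (34, [("R_GS", 1)], [("R_G", 1), ("Sos", 1)], "koff_Sos_RG", "dissociation"),
    (35, [("R_GS", 1)], [("RP", 1), ("G_S", 1)], "koff_GS_R", "dissociation"),
    (36, [("RP", 1), ("G_S", 1)], [("R_GS", 1)], "kon_GS_R", "association"),
    (37, [("Grb2", 1), ("Sos", 1)], [("G_S", 1)], "kon_GS", "association"),
    (38, [("G_S", 1)], [("Grb2", 1), ("Sos", 1)], "koff_GS", "dissociation"),
    (39, [("R_ShGS", 1), ("RasGDP", 1)], [("R_ShGS_Ras", 1)], "kon_GEF_Ras", "association"),
    (40, [("R_ShGS_Ras", 1)], [("R_ShGS", 1), ("RasGDP", 1)], "koff_GEF_Ras", "dissociation"),
    (41, [("R_ShGS_Ras", 1)], [("R_ShGS", 1), ("RasGTP", 1)], "kexch_Ras", "dissociation"),
    (42, [("R_GS", 1), ("RasGDP", 1)], [("R_GS_Ras", 1)], "kon_GEF_Ras", "association"),
    (43, [("R_GS_Ras", 1)], [("R_GS", 1), ("RasGDP", 1)], "koff_GEF_Ras", "dissociation"),
    (44, [("R_GS_Ras", 1)], [("R_GS", 1), ("RasGTP", 1)], "kexch_Ras", "dissociation"),
    (45, [("GAP", 1), ("RasGTP", 1)], [("GAP_RasGTP", 1)], "kon_GAP", "association"),
    (46, [("GAP_RasGTP", 1)], [("GAP", 1), ("RasGTP", 1)], "koff_GAP", "dissociation"),
    (47, [("GAP_RasGTP", 1)], [("GAP", 1), ("RasGDP", 1)], "kcat_GAP", "dephosphorylation"),
    (48, [("RasGTP", 1)], [("RasGDP", 1)], "khyd_Ras", "dephosphorylation"),
    (49, [("RasGDP", 1), ("Raf", 1)], [("RasGDP_Raf", 1)], "kon_RasGDP_Raf", "association"),
    (50, [("RasGDP_Raf", 1)], [("RasGDP", 1), ("Raf", 1)], "koff_RasGDP_Raf", "dissociation"),
    (51, [("RasGTP", 1), ("Raf", 1)], [("RasGTP_Raf", 1)], "kon_RasGTP_Raf", "association"),
    (52, [("RasGTP_Raf", 1)], [("RasGTP", 1), ("Raf", 1)], "koff_RasGTP_Raf", "dissociation"),
    (53, [("RasGTP_Raf", 1)], [("RasGTP_Raf_a", 1)], "kact_Raf", "phosphorylation"),
    (54, [("RasGTP_Raf_a", 1)], [("RasGTP_Raf", 1)], "kdeact_Raf", "dephosphorylation"),
    (55, [("RasGTP_Raf_a", 1)], [("RasGTP", 1), ("aRaf", 1)], "krel_aRaf", "dissociation"),
    (56, [("RasGTP", 1), ("aRaf", 1)], [("RasGTP_Raf_a", 1)], "kon_aRaf_RasGTP", "association"),
    (57, [("aRaf", 1), ("RafPase", 1)], [("RafPase_aRaf", 1)], "kon_RafPase", "association"),
    (58, [("RafPase_aRaf", 1)], [("aRaf", 1), ("RafPase", 1)], "koff_RafPase", "dissociation"),
    (59, [("RafPase_aRaf", 1)], [("Raf", 1), ("RafPase", 1)], "kcat_RafPase", "dephosphorylation"),
    (60, [("aRaf", 1), ("MEK", 1)], [("aRaf_MEK", 1)], "kon_Raf_MEK", "association"),
    (61, [("aRaf_MEK", 1)], [("aRaf", 1), ("MEK", 1)], "koff_Raf_MEK", "dissociation"),
    (62, [("aRaf_MEK", 1)], [("aRaf", 1), ("pMEK", 1)], "kcat_Raf_MEK", "phosphorylation"),
    (63, [("aRaf", 1), ("pMEK", 1)], [("aRaf_pMEK", 1)], "kon_Raf_MEK", "association"),
    (64, [("aRaf_pMEK", 1)], [("aRaf", 1), ("pMEK", 1)], "koff_Raf_MEK", "dissociation"),
    (65, [("aRaf_pMEK", 1)], [("aRaf", 1), ("ppMEK", 1)], "kcat_Raf_MEK", "phosphorylation"),
    (66, [("MEKPase", 1), ("pMEK", 1)], [("MEKPase_pMEK", 1)], "kon_MEKPase", "association"),
    (67, [("MEKPase_pMEK", 1)], [("MEKPase", 1), ("pMEK", 1)], "koff_MEKPase", "dissociation"),
    (68, [("MEKPase_pMEK", 1)], [("MEKPase", 1), ("MEK", 1)], "kcat_MEKPase", "dephosphorylation"),
    (69, [("MEKPase", 1), ("ppMEK", 1)], [("MEKPase_ppMEK", 1)], "kon_MEKPase", "association"),
    (70, [("MEKPase_ppMEK", 1)], [("MEKPase", 1), ("ppMEK", 1)], "koff_MEKPase", "dissociation"),
    (71, [("MEKPase_ppMEK", 1)], [("MEKPase", 1), ("pMEK", 1)], "kcat_MEKPase", "dephosphorylation"),
    (72, [("ppMEK", 1), ("ERKc", 1)], [("ppMEK_ERK", 1)], "kon_MEK_ERK", "association"),
    (73, [("ppMEK_ERK", 1)], [("ppMEK", 1), ("ERKc", 1)], "koff_MEK_ERK", "dissociation"),
    (74, [("ppMEK_ERK", 1)], [("ppMEK", 1), ("pERKc", 1)], "kcat_MEK_ERK", "phosphorylation"),
    (75, [("ppMEK", 1), ("pERKc", 1)], [("ppMEK_pERK", 1)], "kon_MEK_ERK2", "association"),
    (76, [("ppMEK_pERK", 1)], [("ppMEK", 1), ("pERKc", 1)], "koff_MEK_ERK2", "dissociation"),
    (77, [("ppMEK_pERK", 1)], [("ppMEK", 1), ("ppERKc", 1)], "kcat_MEK_ERK2", "phosphorylation"),
    (78, [("ERKPc", 1), ("pERKc", 1)], [("ERKPc_pERK", 1)], "kon_ERKPc", "association"),
    (79, [("ERKPc_pERK", 1)], [("ERKPc", 1), ("pERKc", 1)], "koff_ERKPc", "dissociation"),
    (80, [("ERKPc_pERK", 1)], [("ERKPc", 1), ("ERKc", 1)], "kcat_ERKPc", "dephosphorylation"),
    (81, [("ERKPc", 1), ("ppERKc", 1)], [("ERKPc_ppERK", 1)], "kon_ERKPc", "association"),
    (82, [("ERKPc_ppERK", 1)], [("ERKPc", 1), ("ppERKc", 1)], "koff_ERKPc", "dissociation"),
    (83, [("ERKPc_ppERK", 1)], [("ERKPc", 1), ("pERKc", 1)], "kcat_ERKPc", "dephosphorylation"),
    (84, [("ppERKc", 1), ("Sos", 1)], [("ppERK_Sos", 1)], "kon_ppERK_Sos", "association"),
    (85, [("ppERK_Sos", 1)], [("ppERKc", 1), ("Sos", 1)], "koff_ppERK_Sos", "dissociation"),
    (86, [("ppERK_Sos", 1)], [("ppERKc", 1), ("pSos", 1)], "kcat_ppERK_Sos", "phosphorylation"),
    (87, [("pSos", 1), ("SosPase", 1)], [("SosPase_pSos", 1)], "kon_SosPase", "association"),
    (88, [("SosPase_pSos", 1)], [("pSos", 1), ("SosPase", 1)], "koff_SosPase", "dissociation"),
    (89, [("SosPase_pSos", 1)], [("Sos", 1), ("SosPase", 1)], "kcat_SosPase", "dephosphorylation"),
    (90, [("ERKPn", 1), ("pERKn", 1)], [("ERKPn_pERK", 1)], "kon_ERKPn", "association"),
    (91, [("ERKPn_pERK", 1)], [("ERKPn", 1), ("pERKn", 1)], "koff_ERKPn", "dissociation"),
    (92, [("ERKPn_pERK", 1)], [("ERKPn", 1), ("ERKn", 1)], "kcat_ERKPn", "dephosphorylation"),
    (93, [("ERKPn", 1), ("ppERKn", 1)], [("ERKPn_ppERK", 1)], "kon_ERKPn", "association"),
    (94, [("ERKPn_ppERK", 1)], [("ERKPn", 1), ("ppERKn", 1)], "koff_ERKPn", "dissociation"),
    (95, [("ERKPn_ppERK", 1)], [("ERKPn", 1), ("pERKn", 1)], "kcat_ERKPn", "dephosphorylation"),
    # 96-125: ERK-NPC transport, generated in build_network()
    (126, [("NPCPase", 1), ("pNPC", 1)], [("NPCPase_pNPC", 1)], "kon_NPCPase", "association"),
    (127, [("NPCPase_pNPC", 1)], [("NPCPase", 1), ("pNPC", 1)], "koff_NPCPase", "dissociation"),
    (128, [("NPCPase_pNPC", 1)], [("NPCPase", 1), ("NPC", 1)], "kcat_NPCPase", "dephosphorylation"),
    (129, [("NPCPase", 1), ("ppNPC", 1)], [("NPCPase_ppNPC", 1)], "kon_NPCPase", "association"),
    (130, [("NPCPase_ppNPC", 1)], [("NPCPase", 1), ("ppNPC", 1)], "koff_NPCPase", "dissociation"),
    (131, [("NPCPase_ppNPC", 1)], [("NPCPase", 1), ("pNPC", 1)], "kcat_NPCPase", "dephosphorylation"),
    (132, [("pMEK", 1)], [("MEK", 1)], "kbasal_pMEK", "dephosphorylation"),
    (133, [("ppMEK", 1)], [("pMEK", 1)], "kbasal_ppMEK", "dephosphorylation"),
    (134, [("pERKc", 1)], [("ERKc", 1)], "kbasal_pERKc", "dephosphorylation"),
    (135, [("ppERKc", 1)], [("pERKc", 1)], "kbasal_ppERKc", "dephosphorylation"),
    (136, [("pERKn", 1)], [("ERKn", 1)], "kbasal_pERKn", "dephosphorylation"),
    # 137-144: ERK-mediated NPC phosphorylation (the knockout set)
    (137, [("ppERKn", 1), ("NPC", 1)], [("ppERKn_NPC", 1)], "kon_NPCphos1", "phosphorylation"),
    (138, [("ppERKn_NPC", 1)], [("ppERKn", 1), ("NPC", 1)], "koff_NPCphos1", "phosphorylation"),
    (139, [("ppERKn_NPC", 1)], [("ppERKn", 1), ("pNPC", 1)], "kcat_NPCphos1", "phosphorylation"),
    (140, [("ppERKn", 1), ("pNPC", 1)], [("ppERKn_pNPC", 1)], "kon_NPCphos2", "phosphorylation"),
    (141, [("ppERKn_pNPC", 1)], [("ppERKn", 1), ("pNPC", 1)], "koff_NPCphos2", "phosphorylation"),
    (142, [("ppERKn_pNPC", 1)], [("ppERKn", 1), ("ppNPC", 1)], "kcat_NPCphos2", "phosphorylation"),
    (143, [("pERKn", 1), ("NPC", 1)], [("pERKn", 1), ("pNPC", 1)], "kdirect_NPCphos1", "phosphorylation"),
    (144, [("pERKn", 1), ("pNPC", 1)], [("pERKn", 1), ("ppNPC", 1)], "kdirect_NPCphos2", "phosphorylation"),
    (145, [("pNPC", 1)], [("NPC", 1)], "kbasal_pNPC", "dephosphorylation"),
    (146, [("ppNPC", 1)], [("pNPC", 1)], "kbasal_ppNPC", "dephosphorylation"),
    (147, [("pSos", 1)], [("Sos", 1)], "kbasal_pSos", "dephosphorylation"),
    (148, [("aRaf", 1)], [("Raf", 1)], "kbasal_Raf_deact", "dephosphorylation"),
    (149, [("RasGTP_Raf_a", 1)], [("RasGDP", 1), ("aRaf", 1)], "khyd_Rafa", "dissociation"),
    (150, [("Raf", 1)], [("aRaf", 1)], "kbasal_Raf_act", "phosphorylation"),
]

_ERK_STATES = [("ERK", "ERKc", "ERKn"), ("pERK", "pERKc", "pERKn"), ("ppERK", "ppERKc", "ppERKn")]
_NPC_STATES = ["NPC", "pNPC", "ppNPC"]


def _transport_reactions(params: dict[str, float]):
    """ERK import/export through the pore, reactions 96-125.

    Bidirectional through NPC and pNPC (4 reactions per pair: cytoplasmic
    binding, nuclear release, nuclear binding, cytoplasmic release);
    export-only through ppNPC (2 reactions per ERK state).
    """
    reactions: list[tuple[int, list, list, str, str]] = []
    table: list[dict] = []
    idx = 96
    for ename, cyt, nuc in _ERK_STATES:
        pref = "ERK" if ename == "ERK" else "pERK"  # phospho-ERK share transport rates
        for npc in ("NPC", "pNPC"):
            comp = f"T_{ename}_{npc}"
            r_import = [idx, idx + 1]
            reactions += [
                (idx, [(cyt, 1), (npc, 1)], [(comp, 1)], f"t_bindc_{pref}", "translocation"),
                (idx + 1, [(comp, 1)], [(nuc, 1), (npc, 1)], f"t_reln_{pref}", "translocation"),
                (idx + 2, [(nuc, 1), (npc, 1)], [(comp, 1)], f"t_bindn_{pref}", "translocation"),
                (idx + 3, [(comp, 1)], [(cyt, 1), (npc, 1)], f"t_relc_{pref}", "translocation"),
            ]
            table += [
                {"erk_state": ename, "npc_state": npc, "direction": "import",
                 "reactions": r_import},
                {"erk_state": ename, "npc_state": npc, "direction": "export",
                 "reactions": [idx + 2, idx + 3]},
            ]
            idx += 4
    for ename, cyt, nuc in _ERK_STATES:
        comp = f"T_{ename}_ppNPC"
        reactions += [
            (idx, [(nuc, 1), ("ppNPC", 1)], [(comp, 1)], "t_bindn_ppNPC", "translocation"),
            (idx + 1, [(comp, 1)], [(cyt, 1), ("ppNPC", 1)], "t_relc_ppNPC", "translocation"),
        ]
        table.append(
            {"erk_state": ename, "npc_state": "ppNPC", "direction": "export",
             "reactions": [idx, idx + 1]}
        )
        idx += 2
    assert idx == 126
    return reactions, table


#: species containing at least one phosphorylated ERK moiety
_PERK_SPECIES = [
    "pERKc", "ppERKc", "ppMEK_pERK", "ERKPc_pERK", "ERKPc_ppERK", "ppERK_Sos",
    "pERKn", "ppERKn", "ERKPn_pERK", "ERKPn_ppERK", "ppERKn_NPC", "ppERKn_pNPC",
    "T_pERK_NPC", "T_pERK_pNPC", "T_pERK_ppNPC",
    "T_ppERK_NPC", "T_ppERK_pNPC", "T_ppERK_ppNPC",
]

#: species counted as nuclear ERK (pore-bound transport complexes excluded)
_NUCLEAR_ERK_SPECIES = [
    "ERKn", "pERKn", "ppERKn", "ERKPn_pERK", "ERKPn_ppERK",
    "ppERKn_NPC", "ppERKn_pNPC",
]

PROTEIN_GROUPS = {
    "EGFR": ["EGFR"],
    "Shc": ["Shc"],
    "Grb2": ["Grb2"],
    "Sos": ["Sos"],
    "Ras": ["RasGDP"],
    "GAP": ["GAP"],
    "Raf": ["Raf"],
    "MEK": ["MEK"],
    "ERK": ["ERKc", "ERKn"],
    "RPase": ["RPase"],
    "RafPase": ["RafPase"],
    "MEKPase": ["MEKPase"],
    "ERKPase": ["ERKPc", "ERKPn"],
    "SosPase": ["SosPase"],
    "NPCPase": ["NPCPase"],
    "NPC": ["NPC"],
}


def build_network(
    params: dict[str, float] | None = None,
    initial_counts: dict[str, int] | None = None,
) -> ReactionNetwork:
    """Assemble the 78-species / 150-reaction EGF-ERK-NPC network.

    ``params`` overrides named rate constants; ``initial_counts`` overrides
    nominal initial molecule numbers of named species.
    """
    p = dict(PARAMS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise KeyError(f"unknown rate parameters: {sorted(unknown)}")
        p.update(params)
    counts = {sid: n for sid, _, n in SPECIES}
    if initial_counts:
        unknown = set(initial_counts) - set(counts)
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        counts.update(initial_counts)

    transport, table = _transport_reactions(p)
    raw = REACTIONS + transport
    raw.sort(key=lambda r: r[0])
    species = [
        Species(id=sid, compartment=comp, initial_count=counts[sid],
                clamped=(sid == "EGF"))
        for sid, comp, _ in SPECIES
    ]
    reactions = [
        Reaction(
            index=i,
            reactants=tuple(r),
            products=tuple(pr),
            rate_name=name,
            rate_constant=p[name],
            tag=tag,
        )
        for i, r, pr, name, tag in raw
    ]
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        volumes=dict(VOLUMES),
        name="egf_erk_npc",
        description=(
            "EGF-ERK-NPC signalling network with autoregulatory control of "
            "ERK nuclear translocation; synthetic calibrated reconstruction "
            "(rate constants fitted to published dose-response "
            "characteristics, not individually measured)."
        ),
        observables={
            "pERK": {s: 1.0 for s in _PERK_SPECIES},
            "nuclear_ERK": {s: 1.0 for s in _NUCLEAR_ERK_SPECIES},
        },
        protein_groups={k: list(v) for k, v in PROTEIN_GROUPS.items()},
        erk_transport=table,
    )
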