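"""Programmatic builder for the bundled EGF -> PI3K-Akt -> IKK -> NF-kB network.

The network has four functional modules:

* receptor      -- EGF binding to EGFR, dimerization, autophosphorylation
                   (Michaelis-Menten at the receptor level), internalization,
                   recycling, degradation and synthesis;
* pi3k_akt      -- PI3K recruitment to active receptor, PIP2 -> PIP3
                   catalysis, PTEN-catalyzed PIP3 dephosphorylation,
                   PIP3-mediated membrane recruitment of Akt, two-site
                   activation (Thr308 by PDK1, Ser473 by a PDK2 activity),
                   and PP2A-catalyzed deactivation;
* coupling      -- a single mass-action step in which phospho-Akt activates
                   the IKK complex.  Its rate constant is the unknown the
                   ensemble stage samples;
* nfkb          -- an IkBa-only negative-feedback loop: active IKK
                   phosphorylates IkBa free and in complex with NF-kB,
                   phospho-IkBa is degraded, NF-kB translocates to the
                   nucleus and induces IkBa transcription, newly made IkBa
                   re-sequesters NF-kB and exports it.

Counts are fixed at 42 species and 96 reactions; a unit test locks them.
Nominal rate constants and concentrations follow the order of magnitude of
the canonical receptor-PI3K and IkB/NF-kB kinetic models this family of
networks descends from, expressed in nM and hours.  The shipped
models/baseline.json stores this network with initial concentrations relaxed
to the unstimulated steady state (see scripts/rebuild_baseline.py).
"""

from __future__ import annotations

from .network import RateLaw, Reaction, ReactionNetwork, Species

# (id, human name, compartment, initial nM before pre-equilibration, is_input)
SPECIES: list[tuple[str, str, str, float, bool]] = [
    # receptor module
    ("EGF", "epidermal growth factor", "extracellular", 0.0, True),
    ("EGFR", "EGF receptor", "membrane", 100.0, False),
    ("EGF_EGFR", "EGF-bound receptor", "membrane", 0.0, False),
    ("EGF_EGFR2", "ligand-bound receptor dimer", "membrane", 0.0, False),
    ("pEGFR", "autophosphorylated receptor dimer", "membrane", 0.0, False),
    ("pEGFR_i", "internalized phospho-receptor", "cytoplasm", 0.0, False),
    ("EGFR_i", "internalized receptor", "cytoplasm", 0.0, False),
    ("EGF_EGFR_i", "internalized ligand-bound receptor", "cytoplasm", 0.0, False),
    # PI3K-Akt module
    ("PI3K", "PI3K (p85/p110)", "cytoplasm", 20.0, False),
    ("pEGFR_PI3K", "receptor-PI3K complex", "membrane", 0.0, False),
    ("PI3K_a", "active PI3K", "membrane", 0.0, False),
    ("PIP2", "PI(4,5)P2", "membrane", 500.0, False),
    ("PIP3", "PI(3,4,5)P3", "membrane", 0.0, False),
    ("PI3Ka_PIP2", "active PI3K-PIP2 complex", "membrane", 0.0, False),
    ("PTEN", "PTEN lipid phosphatase", "cytoplasm", 25.0, False),
    ("Akt", "Akt", "cytoplasm", 100.0, False),
    ("Akt_m", "PIP3-docked Akt", "membrane", 0.0, False),
    ("PDK1", "PDK1", "cytoplasm", 50.0, False),
    ("PDK1_Akt_m", "PDK1-Akt complex", "membrane", 0.0, False),
    ("Akt_m_p308", "membrane Akt pThr308", "membrane", 0.0, False),
    ("PDK2", "Ser473 kinase (PDK2 activity)", "cytoplasm", 50.0, False),
    ("PDK2_Akt_m_p308", "PDK2-Akt(pT308) complex", "membrane", 0.0, False),
    ("pAkt_m", "membrane phospho-Akt (pT308/pS473)", "membrane", 0.0, False),
    ("pAkt", "cytoplasmic phospho-Akt", "cytoplasm", 0.0, False),
    ("PP2A", "PP2A phosphatase", "cytoplasm", 5.5, False),
    ("PP2A_pAkt", "PP2A-pAkt complex", "cytoplasm", 0.0, False),
    ("PP2A_pAkt_m", "PP2A-pAkt membrane complex", "membrane", 0.0, False),
    # NF-kB module
    ("IKK", "IKK complex, inactive", "cytoplasm", 100.0, False),
    ("IKKa", "IKK complex, active", "cytoplasm", 0.0, False),
    ("IKKi", "IKK complex, refractory", "cytoplasm", 0.0, False),
    ("IKKa_IkBa", "IKKa-IkBa complex", "cytoplasm", 0.0, False),
    ("IKKa_IkBaNFkB", "IKKa-(IkBa:NF-kB) complex", "cytoplasm", 0.0, False),
    ("IkBa", "IkBa, free cytoplasmic", "cytoplasm", 2.0, False),
    ("pIkBa", "phospho-IkBa", "cytoplasm", 0.0, False),
    ("NFkB", "NF-kB, free cytoplasmic", "cytoplasm", 0.0, False),
    ("IkBa_NFkB", "IkBa:NF-kB complex", "cytoplasm", 100.0, False),
    ("pIkBa_NFkB", "phospho-IkBa:NF-kB complex", "cytoplasm", 0.0, False),
    ("NFkB_n", "NF-kB, nuclear", "nucleus", 0.0, False),
    ("IkBa_n", "IkBa, nuclear", "nucleus", 0.0, False),
    ("IkBa_NFkB_n", "nuclear IkBa:NF-kB complex", "nucleus", 0.0, False),
    ("tIkBa_n", "IkBa transcript, nuclear", "nucleus", 0.0, False),
    ("tIkBa", "IkBa transcript, cytoplasmic", "cytoplasm", 0.0, False),
]

# (id, reactants, products, law, module); law is ("ma", k) or ("mm", Vmax, Km)
REACTIONS: list[tuple] = [
    # ---------------- receptor ----------------
    ("egf_binding", [("EGF", 1), ("EGFR", 1)], [("EGF_EGFR", 1)], ("ma", 10.0), "receptor"),
    ("egf_unbinding", [("EGF_EGFR", 1)], [("EGF", 1), ("EGFR", 1)], ("ma", 10.0), "receptor"),
    ("receptor_dimerization", [("EGF_EGFR", 2)], [("EGF_EGFR2", 1)], ("ma", 2.0), "receptor"),
    ("dimer_separation", [("EGF_EGFR2", 1)], [("EGF_EGFR", 2)], ("ma", 40.0), "receptor"),
    ("receptor_autophos", [("EGF_EGFR2", 1)], [("pEGFR", 1)], ("mm", 6000.0, 30.0), "receptor"),
    ("receptor_dephos", [("pEGFR", 1)], [("EGF_EGFR2", 1)], ("mm", 2500.0, 30.0), "receptor"),
    ("pegfr_internalization", [("pEGFR", 1)], [("pEGFR_i", 1)], ("ma", 3.0), "receptor"),
    ("pegfr_recycling", [("pEGFR_i", 1)], [("pEGFR", 1)], ("ma", 0.3), "receptor"),
    ("endosomal_dephos", [("pEGFR_i", 1)], [("EGFR_i", 2), ("EGF", 2)], ("mm", 400.0, 40.0), "receptor"),
    ("egfr_i_recycling", [("EGFR_i", 1)], [("EGFR", 1)], ("ma", 2.0), "receptor"),
    ("pegfr_i_degradation", [("pEGFR_i", 1)], [], ("ma", 0.8), "receptor"),
    ("egfr_synthesis", [], [("EGFR", 1)], ("ma", 2.0), "receptor"),
    ("egfr_turnover", [("EGFR", 1)], [], ("ma", 0.02), "receptor"),
    ("bound_internalization", [("EGF_EGFR", 1)], [("EGF_EGFR_i", 1)], ("ma", 0.3), "receptor"),
    ("bound_recycling", [("EGF_EGFR_i", 1)], [("EGF_EGFR", 1)], ("ma", 1.0), "receptor"),
    ("endosomal_ligand_loss", [("EGF_EGFR_i", 1)], [("EGFR_i", 1), ("EGF", 1)], ("ma", 2.0), "receptor"),
    ("bound_i_degradation", [("EGF_EGFR_i", 1)], [], ("ma", 0.1), "receptor"),
    ("egfr_i_degradation", [("EGFR_i", 1)], [], ("ma", 0.05), "receptor"),
    ("dimer_ligand_loss", [("EGF_EGFR2", 1)], [("EGF", 2), ("EGFR", 2)], ("ma", 0.05), "receptor"),
    ("dimer_internalization", [("EGF_EGFR2", 1)], [("EGF_EGFR_i", 2)], ("ma", 0.1), "receptor"),
    # ---------------- PI3K-Akt ----------------
    ("pi3k_recruitment", [("pEGFR", 1), ("PI3K", 1)], [("pEGFR_PI3K", 1)], ("ma", 2.0), "pi3k_akt"),
    ("pi3k_release", [("pEGFR_PI3K", 1)], [("pEGFR", 1), ("PI3K", 1)], ("ma", 2.0), "pi3k_akt"),
    ("pi3k_activation", [("pEGFR_PI3K", 1)], [("pEGFR", 1), ("PI3K_a", 1)], ("ma", 60.0), "pi3k_akt"),
    ("pi3k_deactivation", [("PI3K_a", 1)], [("PI3K", 1)], ("ma", 30.0), "pi3k_akt"),
    ("pi3k_internal_release", [("pEGFR_PI3K", 1)], [("pEGFR_i", 1), ("PI3K", 1)], ("ma", 0.5), "pi3k_akt"),
    ("pi3k_pip2_binding", [("PI3K_a", 1), ("PIP2", 1)], [("PI3Ka_PIP2", 1)], ("ma", 0.1), "pi3k_akt"),
    ("pi3k_pip2_release", [("PI3Ka_PIP2", 1)], [("PI3K_a", 1), ("PIP2", 1)], ("ma", 10.0), "pi3k_akt"),
    ("pip3_production", [("PI3Ka_PIP2", 1)], [("PI3K_a", 1), ("PIP3", 1)], ("ma", 360.0), "pi3k_akt"),
    ("pten_pip3_dephos", [("PTEN", 1), ("PIP3", 1)], [("PTEN", 1), ("PIP2", 1)], ("ma", 1.2), "pi3k_akt"),
    ("basal_pip3_production", [("PIP2", 1)], [("PIP3", 1)], ("ma", 1e-6), "pi3k_akt"),
    ("pip3_turnover", [("PIP3", 1)], [], ("ma", 0.05), "pi3k_akt"),
    ("akt_recruitment", [("Akt", 1), ("PIP3", 1)], [("Akt_m", 1)], ("ma", 0.3), "pi3k_akt"),
    ("akt_release", [("Akt_m", 1)], [("Akt", 1), ("PIP3", 1)], ("ma", 12.0), "pi3k_akt"),
    ("pdk1_binding", [("PDK1", 1), ("Akt_m", 1)], [("PDK1_Akt_m", 1)], ("ma", 2.0), "pi3k_akt"),
    ("pdk1_release", [("PDK1_Akt_m", 1)], [("PDK1", 1), ("Akt_m", 1)], ("ma", 10.0), "pi3k_akt"),
    ("akt_phos_t308", [("PDK1_Akt_m", 1)], [("PDK1", 1), ("Akt_m_p308", 1)], ("ma", 120.0), "pi3k_akt"),
    ("pdk2_binding", [("PDK2", 1), ("Akt_m_p308", 1)], [("PDK2_Akt_m_p308", 1)], ("ma", 2.0), "pi3k_akt"),
    ("pdk2_release", [("PDK2_Akt_m_p308", 1)], [("PDK2", 1), ("Akt_m_p308", 1)], ("ma", 10.0), "pi3k_akt"),
    ("akt_phos_s473", [("PDK2_Akt_m_p308", 1)], [("PDK2", 1), ("pAkt_m", 1)], ("ma", 120.0), "pi3k_akt"),
    ("pakt_release", [("pAkt_m", 1)], [("pAkt", 1), ("PIP3", 1)], ("ma", 30.0), "pi3k_akt"),
    ("pakt_rebinding", [("pAkt", 1), ("PIP3", 1)], [("pAkt_m", 1)], ("ma", 0.01), "pi3k_akt"),
    ("pp2a_pakt_binding", [("PP2A", 1), ("pAkt", 1)], [("PP2A_pAkt", 1)], ("ma", 1.0), "pi3k_akt"),
    ("pp2a_pakt_release", [("PP2A_pAkt", 1)], [("PP2A", 1), ("pAkt", 1)], ("ma", 10.0), "pi3k_akt"),
    ("pakt_dephos", [("PP2A_pAkt", 1)], [("PP2A", 1), ("Akt", 1)], ("ma", 100.0), "pi3k_akt"),
    ("pp2a_paktm_binding", [("PP2A", 1), ("pAkt_m", 1)], [("PP2A_pAkt_m", 1)], ("ma", 0.5), "pi3k_akt"),
    ("pp2a_paktm_release", [("PP2A_pAkt_m", 1)], [("PP2A", 1), ("pAkt_m", 1)], ("ma", 10.0), "pi3k_akt"),
    ("paktm_dephos", [("PP2A_pAkt_m", 1)], [("PP2A", 1), ("Akt_m", 1)], ("ma", 100.0), "pi3k_akt"),
    ("basal_pakt_dephos", [("pAkt", 1)], [("Akt", 1)], ("ma", 0.2), "pi3k_akt"),
    ("basal_paktm_dephos", [("pAkt_m", 1)], [("Akt_m", 1)], ("ma", 0.2), "pi3k_akt"),
    ("basal_p308_dephos", [("Akt_m_p308", 1)], [("Akt_m", 1)], ("ma", 0.2), "pi3k_akt"),
    ("pi3k_synthesis", [], [("PI3K", 1)], ("ma", 0.4), "pi3k_akt"),
    ("pi3k_turnover", [("PI3K", 1)], [], ("ma", 0.02), "pi3k_akt"),
    ("pi3k_a_turnover", [("PI3K_a", 1)], [], ("ma", 0.02), "pi3k_akt"),
    ("pip2_synthesis", [], [("PIP2", 1)], ("ma", 5.0), "pi3k_akt"),
    ("pip2_turnover", [("PIP2", 1)], [], ("ma", 0.01), "pi3k_akt"),
    # ---------------- coupling ----------------
    ("akt_ikk_coupling", [("pAkt", 1), ("IKK", 1)], [("pAkt", 1), ("IKKa", 1)], ("ma", 1.0), "coupling"),
    # ---------------- NF-kB ----------------
    ("ikk_inactivation", [("IKKa", 1)], [("IKKi", 1)], ("ma", 20.0), "nfkb"),
    ("ikka_dephos", [("IKKa", 1)], [("IKK", 1)], ("ma", 40.0), "nfkb"),
    ("ikk_recycling", [("IKKi", 1)], [("IKK", 1)], ("ma", 4.0), "nfkb"),
    ("ikk_synthesis", [], [("IKK", 1)], ("ma", 1.2), "nfkb"),
    ("ikk_turnover", [("IKK", 1)], [], ("ma", 0.012), "nfkb"),
    ("ikka_turnover", [("IKKa", 1)], [], ("ma", 0.012), "nfkb"),
    ("ikki_turnover", [("IKKi", 1)], [], ("ma", 0.012), "nfkb"),
    ("ikka_ikba_binding", [("IKKa", 1), ("IkBa", 1)], [("IKKa_IkBa", 1)], ("ma", 1.6), "nfkb"),
    ("ikka_ikba_release", [("IKKa_IkBa", 1)], [("IKKa", 1), ("IkBa", 1)], ("ma", 1.0), "nfkb"),
    ("ikba_phosphorylation", [("IKKa_IkBa", 1)], [("IKKa", 1), ("pIkBa", 1)], ("ma", 20.0), "nfkb"),
    ("ikka_complex_binding", [("IKKa", 1), ("IkBa_NFkB", 1)], [("IKKa_IkBaNFkB", 1)], ("ma", 2.0), "nfkb"),
    ("ikka_complex_release", [("IKKa_IkBaNFkB", 1)], [("IKKa", 1), ("IkBa_NFkB", 1)], ("ma", 1.0), "nfkb"),
    ("complex_ikba_phosphorylation", [("IKKa_IkBaNFkB", 1)], [("IKKa", 1), ("pIkBa_NFkB", 1)], ("ma", 20.0), "nfkb"),
    ("pikba_degradation", [("pIkBa", 1)], [], ("ma", 30.0), "nfkb"),
    ("pikba_complex_degradation", [("pIkBa_NFkB", 1)], [("NFkB", 1)], ("ma", 30.0), "nfkb"),
    ("pikba_dephos", [("pIkBa", 1)], [("IkBa", 1)], ("ma", 0.6), "nfkb"),
    ("pikba_complex_dephos", [("pIkBa_NFkB", 1)], [("IkBa_NFkB", 1)], ("ma", 0.6), "nfkb"),
    ("pikba_nfkb_binding", [("NFkB", 1), ("pIkBa", 1)], [("pIkBa_NFkB", 1)], ("ma", 10.0), "nfkb"),
    ("pikba_nfkb_release", [("pIkBa_NFkB", 1)], [("NFkB", 1), ("pIkBa", 1)], ("ma", 1.0), "nfkb"),
    ("ikba_nfkb_binding", [("NFkB", 1), ("IkBa", 1)], [("IkBa_NFkB", 1)], ("ma", 30.0), "nfkb"),
    ("ikba_nfkb_release", [("IkBa_NFkB", 1)], [("NFkB", 1), ("IkBa", 1)], ("ma", 0.05), "nfkb"),
    ("nfkb_nuclear_import", [("NFkB", 1)], [("NFkB_n", 1)], ("ma", 60.0), "nfkb"),
    ("nfkb_nuclear_export", [("NFkB_n", 1)], [("NFkB", 1)], ("ma", 0.1), "nfkb"),
    ("ikba_nuclear_import", [("IkBa", 1)], [("IkBa_n", 1)], ("ma", 3.0), "nfkb"),
    ("ikba_nuclear_export", [("IkBa_n", 1)], [("IkBa", 1)], ("ma", 12.0), "nfkb"),
    ("nuclear_complex_binding", [("NFkB_n", 1), ("IkBa_n", 1)], [("IkBa_NFkB_n", 1)], ("ma", 30.0), "nfkb"),
    ("nuclear_complex_release", [("IkBa_NFkB_n", 1)], [("NFkB_n", 1), ("IkBa_n", 1)], ("ma", 0.05), "nfkb"),
    ("complex_nuclear_export", [("IkBa_NFkB_n", 1)], [("IkBa_NFkB", 1)], ("ma", 50.0), "nfkb"),
    ("complex_nuclear_import", [("IkBa_NFkB", 1)], [("IkBa_NFkB_n", 1)], ("ma", 0.2), "nfkb"),
    ("induced_transcription", [("NFkB_n", 1)], [("NFkB_n", 1), ("tIkBa_n", 1)], ("ma", 0.12), "nfkb"),
    ("basal_transcription", [], [("tIkBa_n", 1)], ("ma", 0.02), "nfkb"),
    ("transcript_export", [("tIkBa_n", 1)], [("tIkBa", 1)], ("ma", 10.0), "nfkb"),
    ("transcript_decay", [("tIkBa", 1)], [], ("ma", 2.0), "nfkb"),
    ("nuclear_transcript_decay", [("tIkBa_n", 1)], [], ("ma", 2.0), "nfkb"),
    ("translation", [("tIkBa", 1)], [("tIkBa", 1), ("IkBa", 1)], ("ma", 36.0), "nfkb"),
    ("ikba_constitutive_synthesis", [], [("IkBa", 1)], ("ma", 12.0), "nfkb"),
    ("ikba_degradation", [("IkBa", 1)], [], ("ma", 0.6), "nfkb"),
    ("ikba_n_degradation", [("IkBa_n", 1)], [], ("ma", 0.6), "nfkb"),
    ("complex_ikba_turnover", [("IkBa_NFkB", 1)], [("NFkB", 1)], ("ma", 0.01), "nfkb"),
    ("nuclear_complex_ikba_turnover", [("IkBa_NFkB_n", 1)], [("NFkB_n", 1)], ("ma", 0.01), "nfkb"),
]


def build_network(metadata: dict | None = None) -> ReactionNetwork:
    """Assemble the baseline network from the tables above (raw initials)."""
    species = [
        Species(id=i, name=n, compartment=c, initial_nM=x0, is_input=inp)
        for i, n, c, x0, inp in SPECIES
    ]
    reactions = []
    for rid, reac, prod, law, module in REACTIONS:
        if law[0] == "ma":
            rl = RateLaw(kind="mass_action", k=law[1])
        else:
            rl = RateLaw(kind="michaelis_menten", vmax=law[1], km=law[2])
        reactions.append(
            Reaction(id=rid, reactants=tuple(reac), products=tuple(prod), rate_law=rl, module=module)
        )
    meta = {
        "name": "egf_pi3k_akt_ikk_nfkb_baseline",
        "units": "concentration nM, time h",
        "provenance": (
            "reconstructed baseline; receptor and PI3K arm follow canonical "
            "EGFR/PI3K kinetic models, the NF-kB arm follows the IkBa-only "
            "negative-feedback architecture of canonical IKK-IkB-NF-kB models"
        ),
    }
    if metadata:
        meta.update(metadata)
    net = ReactionNetwork(species=species, reactions=reactions, metadata=meta)
    assert len(net.species) == 42, len(net.species)
    assert len(net.reactions) == 96, len(net.reactions)
    return net
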