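# Default item registry: the three pharmaceutical-regulation indices built
# from the WHO Country Pharmaceutical Situation survey instrument.
# Each index block lists its binary items in canonical order; `anchor` names
# the item whose discrimination is constrained positive to fix the sign of
# the latent scale.
indices:
  infrastructure:
    title: State Regulatory Infrastructure
    anchor: "5.05.03"
    items:
      - id: "3.01.04"
        label: A national medicines policy official document exists
      - id: "3.01.12"
        label: Pharmaceutical policy implementation is regularly monitored/assessed
      - id: "3.01.14"
        label: Policy to manage and sanction conflicts of interest in pharmaceutical affairs
      - id: "3.01.16"
        label: Whistle-blowing mechanism for wrongdoing in the pharmaceutical sector
      - id: "5.01.01"
        label: Legal provisions establish the powers and responsibilities of the MRA
      - id: "5.01.02"
        label: A Medicines Regulatory Authority (MRA) exists
      - id: "5.01.04.02"
        label: The MRA is a semi-autonomous agency
      - id: "5.01.10"
        label: Assessment of the medicines regulatory system conducted in the last five years
      - id: "5.01.11"
        label: The MRA gets funds from the regular government budget
      - id: "5.01.15"
        label: The MRA uses a computerized information management system
      - id: "5.02.15S"
        label: Experts in registration decisions must declare potential conflicts of interest
      - id: "5.05.03"
        label: Good Manufacturing Practices (GMP) requirements are published by the government
      - id: "5.05.07"
        label: National Good Distribution Practice requirements are published by the government
      - id: "5.05.11"
        label: National Good Pharmacy Practice Guidelines are published by the government

  private_market:
    title: Monitoring the Private Market
    anchor: "5.07.01"
    items:
      - id: "5.02.08"
        label: Medicines registration always includes the INN
        aspect: legal_framework
      - id: "5.02.12S"
        label: Legal provisions require publication of Summaries of Product Characteristics
        aspect: legal_framework
      - id: "5.05.01"
        label: Legal provisions require manufacturers to be licensed
        aspect: legal_framework
      - id: "5.05.02"
        label: Legal provisions require manufacturers to comply with GMP
        aspect: legal_framework
      - id: "5.05.05"
        label: Legal provisions require wholesalers and distributors to be licensed
        aspect: legal_framework
      - id: "5.05.06"
        label: Legal provisions require wholesalers and distributors to comply with GDP
        aspect: legal_framework
      - id: "5.05.08"
        label: Legal provisions require pharmacists to be registered
        aspect: legal_framework
      - id: "5.05.09"
        label: Legal provisions require private pharmacies to be licensed
        aspect: legal_framework
      - id: "5.07.01"
        label: Legal provisions control promotion/advertising of prescription medicines
        aspect: legal_framework
      - id: "5.03.05.01"
        label: Local manufacturers are inspected for GMP compliance
        aspect: supply_chain
      - id: "5.03.05.02"
        label: Private wholesalers are inspected
        aspect: supply_chain
      - id: "5.03.05.03"
        label: Retail distributors are inspected
        aspect: supply_chain
      - id: "5.03.05.05"
        label: Pharmacies and dispensing points of health facilities are inspected
        aspect: supply_chain
      - id: "Inspections"
        label: Regularity of inspections
        aspect: supply_chain
        derived:
          sources:
            manufacturers: insp_years_manufacturers
            retail: insp_years_retail
            dispensing: insp_years_dispensing
      - id: "5.04.02"
        label: Legal provisions allow sampling of imported products for testing
        aspect: supply_chain
      - id: "5.04.03"
        label: Legal provisions require importation through authorized ports of entry
        aspect: supply_chain
      - id: "5.04.04"
        label: Legal provisions allow inspection of imported products at ports of entry
        aspect: supply_chain
      - id: "5.05.04"
        label: Legal provisions require importers to be licensed
        aspect: supply_chain
      - id: "5.10.01"
        label: Pharmacovigilance is part of the MRA mandate
        aspect: pharmacovigilance
      - id: "5.10.02"
        label: Marketing authorization holders must monitor safety and report to the MRA
        aspect: pharmacovigilance
      - id: "5.10.03"
        label: Legal provisions on monitoring Adverse Drug Reactions (ADR) exist
        aspect: pharmacovigilance
      - id: "5.10.22S"
        label: Training courses in pharmacovigilance exist
        aspect: pharmacovigilance
      - id: "5.10.05"
        label: An official standardized form for reporting ADRs is used
        aspect: pharmacovigilance
      - id: "5.10.06"
        label: A national ADR database exists
        aspect: pharmacovigilance
      - id: "5.10.10"
        label: A national ADR or pharmacovigilance advisory committee exists
        aspect: pharmacovigilance
      - id: "5.10.16S"
        label: The ADR database is computerized
        aspect: pharmacovigilance

  public_quality:
    title: Public Quality Control
    anchor: "7.10.10.01S"
    items:
      - id: "5.03.05.04"
        label: Public pharmacies and stores are inspected
      - id: "5.03.05.05"
        label: Pharmacies and dispensing points of health facilities are inspected
      - id: "5.05.08"
        label: Legal provisions require pharmacists to be registered
      - id: "5.05.10"
        label: Legal provisions require public pharmacies to be licensed
      - id: "5.06.04.01"
        label: Quality monitoring in the public sector exists (routine sampling)
      - id: "5.06.04.06"
        label: Testing of public program products prior to acceptance/distribution
      - id: "7.01.03"
        label: Public sector requests for tender documents are publicly available
      - id: "7.01.04"
        label: Public sector tender awards are publicly available
      - id: "7.01.05"
        label: A system to prequalify suppliers exists
      - id: "7.01.07S"
        label: A written public sector procurement policy exists
      - id: "7.01.10S"
        label: A process exists to ensure the quality of products procured
      - id: "7.01.11S"
        label: List of samples tested during procurement and results are available
      - id: "7.01.12.01S"
        label: Tenders are nationally competitive
      - id: "7.01.12.02S"
        label: Tenders are internationally competitive
      - id: "7.02.03"
        label: National guidelines on Good Distribution Practices (GDP) exist
      - id: "7.10.10.01S"
        label: Quality assurance includes prequalification of products and suppliers
      - id: "7.10.10.02S"
        label: Explicit criteria and procedures exist for prequalification of suppliers
      - id: "7.10.10.03S"
        label: List of prequalified suppliers and products is publicly available
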