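# Packaged benchmark tables

`cohort_ranks.tsv` — per-epitope rank list for the published 13-patient
validation cohort (1599 assayed SNVs, 19 Elispot-confirmed immunogenic).
The full supplementary rank table is not redistributable here; rank values
were reconstructed from the published per-method top-5 / top-10 / top-20
immunogenic counts (TruNeo 6/10/13, MHCflurry 4/4/8, NetMHCpan4 4/5/10).
Only bin membership (<=5, 6-10, 11-20, >20) is authoritative — exact rank
values inside a bin and the patient assignment of epitopes are arbitrary but
fixed.  Metrics at k in {5, 10, 20} are therefore faithful; other k are not.

`elispot_top10.tsv` — patient-01 top-10 candidate peptides per method with
their Elispot outcomes, transcribed from the published per-peptide table.
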