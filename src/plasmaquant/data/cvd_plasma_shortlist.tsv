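accession	protein_name	n_peptides_discovery	ratio_discovery	p_discovery	n_peptides_test	ratio_test	p_test
Q96M60	Protein FAM227B	2	0.44	7.58E-04	2	0.38	8.11E-03
Q03164	Histone-lysine N-methyltransferase 2A	2	0.38	9.84E-04	2	0.12	8.11E-03
Q9NVW2	E3 ubiquitin-protein ligase RLIM	3	2.66	4.23E-03	4	2.46	8.11E-03
O60494	Cubilin	2	15.19	1.18E-03	2	27.19	1.29E-02
P01023	Alpha-2-macroglobulin	64	2.37	1.27E-03	82	2.50	1.37E-02
Q02880	DNA topoisomerase 2-beta	3	3.86	2.98E-03	9	3.25	1.37E-02
Q8WWI1	LIM domain only protein 7	2	3.26	4.23E-03	2	3.33	2.25E-02
O75665	Oral-facial-digital syndrome 1 protein	2	3.01	1.86E-02	2	3.36	2.25E-02
P36957	Dihydrolipoyllysine-residue succinyltransferase component of 2-oxoglutarate dehydrogenase complex, mitochondrial	2	2.67	4.61E-02	2	5.50	3.53E-02
O75445	Usherin	2	2.50	3.35E-03	5	9.25	5.52E-02
P05546	Heparin cofactor 2	8	2.99	3.36E-03	17	3.99	5.52E-02
Q8IZU0	Protein FAM9B	2	2.36	3.36E-03	2	4.14	5.52E-02
A0AUZ9	KAT8 regulatory NSL complex subunit 1-like protein	2	3.30	1.53E-02	2	2.11	5.52E-02
Q92766	Ras-responsive element-binding protein 1	2	2.31	3.88E-02	2	3.35	6.73E-02
Q5TEZ5	Uncharacterized protein C6orf163	4	2.13	1.25E-02	4	2.28	8.28E-02
P54317	Pancreatic lipase-related protein 2	2	0.01	4.51E-03	3	only_in_controls	9.96E-02
Q9H6S0	Probable ATP-dependent RNA helicase YTHDC2	3	5.23	4.60E-03	6	2.31	1.21E-01
P01266	Thyroglobulin	3	0.33	9.90E-03	4	0.46	1.21E-01
P08185	Corticosteroid-binding globulin	2	2.65	3.26E-02	4	3.35	1.21E-01
Q5T200	Zinc finger CCCH domain-containing protein 13	3	8.07	4.18E-03	3	5.71	1.35E-01
P18428	Lipopolysaccharide-binding protein	5	0.29	7.55E-04	8	0.43	1.71E-01
P98164	Low-density lipoprotein receptor-related protein 2	5	4.00	1.25E-02	10	3.92	1.71E-01
Q5T011	Protein SZT2	2	0.33	1.86E-02	3	0.37	1.71E-01
P04114	Apolipoprotein B-100	68	2.47	3.26E-02	135	2.16	1.71E-01
Q9NS86	LanC-like protein 2	3	2.54	4.64E-02	3	2.76	1.71E-01
Q9H7L9	Sin3 histone deacetylase corepressor complex component SDS3	2	4.70	1.84E-02	4	2.50	2.00E-01
O60884	DnaJ homolog subfamily A member 2	2	6.36	2.67E-03	2	2.21	2.31E-01
Q5T481	RNA-binding protein 20	4	4.84	9.84E-04	4	4.61	2.35E-01
Q5VZL5	Zinc finger MYM-type protein 4	2	0.36	5.30E-03	2	0.38	2.62E-01
O15553	Pyrin	2	11.75	1.72E-03	2	2.65	2.74E-01
Q96PV0	Ras/Rap GTPase-activating protein SynGAP	2	0.15	7.33E-03	3	0.49	3.11E-01
Q8N436	Inactive carboxypeptidase-like protein X2	2	0.46	1.84E-02	3	0.37	3.11E-01
Q14767	Latent-transforming growth factor beta-binding protein 2	4	0.28	7.58E-04	6	0.43	3.15E-01
Q8IWB6	Inactive serine/threonine-protein kinase TEX14	2	4.64	3.84E-02	4	2.43	3.60E-01
Q5T9S5	Coiled-coil domain-containing protein 18	2	0.37	2.01E-02	3	0.25	3.89E-01
Q8N163	Cell cycle and apoptosis regulator protein 2	2	0.21	3.51E-02	3	0.17	3.89E-01
Q9GZU1	Mucolipin-1	2	0.35	1.46E-02	3	0.48	4.10E-01
O43301	Heat shock 70 kDa protein 12A	2	3.16	1.68E-02	2	3.91	4.11E-01
A6NES4	Maestro heat-like repeat-containing protein family member 2A	2	0.28	7.55E-04	3	0.24	6.48E-01
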