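sub_module	mirna_signature	gene_signature
ModuleS1	let-7b;let-7c;let-7f; miR-92b;let-7d;miR-29c	LAMA1-LAMA5;LAMB1-LAMB4; LAMC1-LAMC3;SDC1-SDC4
ModuleS2	miR-590-3p;miR-129-5p;miR-206	BUD31;DDX42;DDX46;DDX5;DHX15; HNRNPA1;HNRNPA1L2;HNRNPA3;HNRNPC; HNRNPK;HNRNPM;HNRNPU;LSM2-LSM7; MAGOH;MAGOHB;NAA38;NCBP1;NCBP2; PCBP1;PHF5A;PLRG1;RB1;PRPF40A;SNRPG;PRPF40B;RBM17;RBM25;RBM8A;RBMX; RBMXL1;SF3B14;SF3B1-SF3B5;SNRNP70; SNRPA1;SNRPB;SNRPB2;TRA2B;SNRPC; SNRPD1-SNRPD3;SNRPE;SNRPF; SR140;SRSF1-SRSF10;TRA2A
ModuleS3	miR-15a;miR-16; miR-646;miR-186; miR-455-5p;miR-628-5p	EGFR;ERBB2;FLT1;FLT4;FZD1-FZD10; IGF1R;ITGB1;ITGB3-ITGB8;KDR;MET; PDGFRA; PDGFRB
ModuleS4	miR-193a-3p;miR-141; miR-544;miR-507; miR-524-5p;miR-586; miR-433;miR-619; miR-548d-5p; miR-525-5p;miR-301a	ANAPC1;ANAPC10;ANAPC11;ANAPC13; ANAPC2;ANAPC4;ANAPC5;ANAPC7;BUB3; CCNB1-CCNB3;CCND1-CCND3;CDC16; CDC23;CDC25B;CDC25C;CDC26;CDC27; CDK4;CDK6;FBXO5;POLA1;POLA2;POLE; POLD1-POLD4;POLE2-POLE4;PRIM1; PRIM2;RRM1;RRM2;RRM2B;UMPS
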