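# Reconstructed 65-SNP linkage panel flanking HBB (hg19). rs-IDs and
# coordinates are synthetic stand-ins for the assay's supplementary table.
id	chrom	pos	ref	alt	maf
rs9906733	chr11	4760288	G	T	0.396
rs3288439	chr11	4761000	G	A	0.499
rs1977695	chr11	4794474	A	T	0.452
rs5157646	chr11	4812733	G	T	0.483
rs5616889	chr11	4836484	C	G	0.435
rs8028700	chr11	4842554	T	A	0.411
rs5854524	chr11	4862926	A	G	0.417
rs8033510	chr11	4914880	C	G	0.473
rs5283533	chr11	4919145	C	T	0.479
rs9596874	chr11	4922928	C	T	0.451
rs2096820	chr11	4945150	G	C	0.481
rs6947726	chr11	4962291	T	G	0.364
rs9010872	chr11	4977222	G	T	0.433
rs3449647	chr11	4978310	T	C	0.429
rs6811240	chr11	4984843	C	G	0.497
rs1063393	chr11	4990304	T	G	0.443
rs3118707	chr11	4996803	C	G	0.437
rs7458956	chr11	5022165	T	G	0.449
rs1377851	chr11	5035375	A	G	0.391
rs8933833	chr11	5056754	C	T	0.414
rs3642147	chr11	5065618	A	G	0.431
rs4188098	chr11	5080125	G	A	0.463
rs8521302	chr11	5082653	G	A	0.369
rs5514468	chr11	5085346	A	C	0.496
rs3752830	chr11	5091578	A	T	0.383
rs4154702	chr11	5113600	T	G	0.406
rs3995356	chr11	5118828	G	A	0.451
rs6645907	chr11	5125606	C	G	0.431
rs1691609	chr11	5129682	A	C	0.478
rs5043709	chr11	5156928	C	A	0.438
rs9768064	chr11	5176569	C	T	0.402
rs7469882	chr11	5177902	C	T	0.471
rs5120233	chr11	5203683	G	C	0.465
rs4473041	chr11	5251609	T	A	0.418
rs9594497	chr11	5274191	C	T	0.467
rs6629055	chr11	5274551	T	G	0.369
rs8942285	chr11	5275005	A	C	0.495
rs8871054	chr11	5284297	C	G	0.435
rs2911969	chr11	5291129	C	A	0.412
rs2375507	chr11	5311574	C	A	0.423
rs9661031	chr11	5315507	T	C	0.364
rs9540756	chr11	5335762	C	A	0.426
rs6871870	chr11	5357960	A	G	0.398
rs9662919	chr11	5368123	G	T	0.45
rs4709108	chr11	5403345	T	G	0.364
rs8099279	chr11	5406077	C	A	0.436
rs6632724	chr11	5407663	T	G	0.468
rs5610208	chr11	5436293	A	T	0.443
rs5021596	chr11	5495694	T	G	0.474
rs3656413	chr11	5498803	G	A	0.458
rs9355519	chr11	5514953	T	G	0.464
rs8621730	chr11	5560583	T	C	0.468
rs4163821	chr11	5591327	C	T	0.492
rs4222737	chr11	5602440	G	T	0.491
rs2921021	chr11	5619421	C	G	0.427
rs3115654	chr11	5626847	G	T	0.466
rs5179376	chr11	5632518	C	G	0.388
rs3302099	chr11	5651461	T	A	0.424
rs7710089	chr11	5667061	G	A	0.375
rs8199640	chr11	5672689	C	T	0.427
rs8319028	chr11	5697798	T	G	0.383
rs1763985	chr11	5727679	C	G	0.431
rs7042462	chr11	5728722	A	T	0.377
rs8089112	chr11	5734835	G	A	0.37
rs3414744	chr11	5737790	A	G	0.386
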