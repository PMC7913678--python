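name,sequence,origin,family,pdb_ids,strand_orientation,quartets,stacking,loops,grooves,tm_highK_C,tm_ms_buffer_C,k_species_pct,cd_comparison,nmr_comparison,topology_conclusion,rating
2GKU,TTGGGTTAGGGTTAGGGTTAGGGA,Human telomere,human-telomeric-and-variants,2GKU,Hybrid-1,3,II,pll,mwnm,67,41,2:100,Idem,Idem + minor peaks,2K+: Same folding as PDB,two-star
2JSM,TAGGGTTAGGGTTAGGGTTAGGG,Human telomere,human-telomeric-and-variants,2JSM,Hybrid-1,3,II,pll,mwnm,64,37,0:6;1:18.7;2:75.3,Idem,Idem + minor peaks,2K+: Same folding as PDB,two-star
2JPZ,TTAGGGTTAGGGTTAGGGTTAGGGTT,Human telomere,human-telomeric-and-variants,2JPZ,Hybrid-2,3,II,llp,mwnm,58,28,0:16.8;1:18.5;2:64.7,"Lower intensity, same shape",Idem + minor peaks,"2K+: Same folding as PDB, but incomplete folding",one-star
2HY9,AAAGGGTTAGGGTTAGGGTTAGGGAA,Human telomere,human-telomeric-and-variants,2HY9,Hybrid-1,3,II,pll,mwnm,59,29,0:17.8;1:19.8;2:62.4,Idem,Idem + minor peaks,"2K+: Same folding as PDB, but incomplete folding",one-star
5YEY,GGGTTAGGGTTAGGGTTTGGG,Artificial variant,human-telomeric-and-variants,5YEY,Antiparallel,3,II,lll,nwnw,71,43,1:16.4;2:83.6,Idem,Idem,2K+: Same folding as PDB,two-star
2KF8,GGGTTAGGGTTAGGGTTAGGGT,Human telomere,human-telomeric-and-variants,2KF8,Antiparallel,2,III,ldl,mnmw,71,41,1:48.8;2:51.2,Less homostacking,Matching satisfactory + minor peaks,2K+: Same folding as PDB,two-star
2KM3,AGGGCTAGGGCTAGGGCTAGGG,Artificial variant,human-telomeric-and-variants,2KM3,Antiparallel,2,III,lll,nwnw,67,38,0:17.2;1:54.0;2:28.8,Lower intensity,Matching satisfactory + minor peaks,"1K+: Same folding as PDB, incomplete folding",one-star
5LQG,TAGGGTTAGGGTTAGGGTTAGG,Human telomere,human-telomeric-and-variants,5LQG,Antiparallel,2,III,ldl,mnmw,53,36,0:14;1:60;2:26,"Lower intensity, same shape",Partially matching + minor peaks,"1K+: Maybe same folding as PDB, but incomplete folding",one-star
21G,GGGTTAGGGTTAGGGTTAGGG,Human telomere,human-telomeric-and-variants,,Mixture,,,,,70,44,1:52.7;2:47.3,Less homostacking,Polymorphic,Polymorphic but resembles 2KF8,cross
22AG,AGGGTTAGGGTTAGGGTTAGGG,Human telomere,human-telomeric-and-variants,,Mixture,,,,,67,41,1:49;2:51,Less homostacking,Polymorphic,Polymorphic but resembles 2KF8,cross
2LK7,TTGGGTGGGTGGGTGGGT,Artificial construct,parallel,2LK7,Parallel,3,I,ppp,mmmm,>75,71,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2LEE,TAGGGCGGGAGGGAGGGAA,N-myc,parallel,2LEE,Parallel,3,I,ppp,mmmm,>75,56,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2M4P,TTGTGGTGGGTGGGTGGGT,Artificial construct,parallel,2M4P,Parallel,3,I,ppp + bulge,mmmm,>75,52,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2LXQ,TAGGGTGGGTTGGGTGGGGAAT,Neisseria gonorrhoeae pilE,parallel,2LXQ,Parallel,3,I,ppp,mmmm,>75,60,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2M27,CGGGGCGGGCCTTGGGCGGGGT,VEGF,parallel,2M27,Parallel,3,I,ppp,mmmm,>75,45,1:9.5;2:90.5,Idem,Idem,2K+: Same folding as PDB,two-star
1XAV,TGAGGGTGGGTAGGGTGGGTAA,c-MYC,parallel,1XAV,Parallel,3,I,ppp,mmmm,>75,54,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2MGN,TGAGGGTGGTGAGGGTGGGGAAGG,Myc2345,parallel,"2A5P,2MGN",Parallel,3,I,ppp,mmmm,70,53,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2LPW,AAGGGTGGGTGTAAGTGTGGGTGGGT,CEB25 Minisatellite,parallel,2LPW,Parallel,3,I,ppp,mmmm,>75,53,2:100,Idem,Idem,2K+: Same folding as PDB,two-star
2LBY,TAGGGAGGGTAGGGAGGGT,Myc1234,parallel,2LBY,Parallel,3,I,ppp,mmmm,>75,44,0:41.3;1:18.2;2:40.5,Lower intensity,Idem + minor peaks,"2K+: Same folding as PDB, but incomplete folding",one-star
2O3M,AGGGAGGGCGCTGGGAGGAGGG,c-kit,parallel,2O3M,Parallel,3,I,pppp,mmmm,65,33,0:20.6;1:11.7;2:67.7,Idem,Idem + minor peaks,"2K+: Same folding as PDB, but incomplete folding",one-star
5NYS,TAGGGACGGGCGGGCAGGGT,Artificial construct,parallel,5NYS,Parallel,3,I,ppp,mmmm,>75,40,0:30.9;1:21.4;2:47.7,"Less intensity, more heterostacking",Idem,"2K+: Same folding as PDB, but incomplete folding according to MS and CD",one-star
2KYP,CGGGCGGGCGCTAGGGAGGGT,c-kit2,parallel,2KYP,Parallel,3,I,ppp,mmmm,60,42,0:58.1;1:27.8;2:14.1,Less homo stacking,Not matching,Incomplete and different folding,cross
2N4Y,CTGGGCGGGACTGGGGAGTGGT,HIV-1 LTR,parallel,2N4Y,Parallel,3,I,ppp+bulge,mmmm,45,<25,0:50.9;1:32.4;2:16.7,Less homo stacking,Not matching,Incomplete and different folding,cross
5I2V,AGGGCGGTGTGGGAATAGGGAA,KRAS,parallel,5I2V,Parallel,3,I,ppp,mmmm,48,<25,0:54.5;1:25.6;2:19.9,Less homo stacking,Matching satisfactory + minor peaks,"May be same folding as PDB, but incomplete folding",cross
2KPR,GGGTGGGGAAGGGGTGGGT,human chl1,other,2KPR,Hybrid,3,II,llpp,ambiguous,>75,53,1:14.4;2:85.6,More heterostacking,Idem,"2K+: Same main structure as PDB, but CD differs",one-star
2LOD,GGGATGGGACACAGGGGACGGG,Artificial construct,other,2LOD,Hybrid,3,II,pdl,mwnm,64,39,0:17.5;1:26.1;2:56.4,Less heterostacking,Idem + minor peaks,"2K+: Maybe same structure as PDB, but incomplete folding and CD differs",one-star
HIV-PRO1,TGGCCTGGGCGGGACTGGG,HIV-1 LTR,other,,Antiparallel,2,III,lll,nwnw,59,29,0:59.5;1:40.5,Less stacking,Not matching,Incomplete and different folding,cross
6GZN,GGGTAGGGAGCGGGAGAGGG,RANKL,other,6GZN,Antiparallel,2,III,ldl,mnmw,,<25,0:35.8;1:33.6;2:30.6,"Less intensity, less homostacking",Not matching,Incomplete and different folding,cross
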