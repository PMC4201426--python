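species,family,order,appendix
sp001,fam01,ord01,3
sp002,fam01,ord01,3
sp003,fam01,ord01,3
sp004,fam01,ord01,3
sp005,fam01,ord01,3
sp006,fam02,ord01,3
sp007,fam02,ord01,1
sp008,fam02,ord01,1
sp009,fam02,ord01,1
sp010,fam02,ord01,1
sp011,fam02,ord01,1
sp012,fam03,ord01,1
sp013,fam03,ord01,2
sp014,fam04,ord02,1
sp015,fam04,ord02,3
sp016,fam04,ord02,3
sp017,fam04,ord02,3
sp018,fam04,ord02,1
sp019,fam04,ord02,3
sp020,fam05,ord02,1
sp021,fam05,ord02,3
sp022,fam05,ord02,3
sp023,fam05,ord02,1
sp024,fam06,ord02,3
sp025,fam06,ord02,3
sp026,fam06,ord02,1
sp027,fam06,ord02,3
sp028,fam06,ord02,2
sp029,fam07,ord03,3
sp030,fam08,ord03,3
sp031,fam08,ord03,3
sp032,fam09,ord04,3
sp033,fam09,ord04,1
sp034,fam09,ord04,3
sp035,fam09,ord04,1
sp036,fam09,ord04,3
sp037,fam09,ord04,2
sp038,fam10,ord04,2
sp039,fam10,ord04,3
sp040,fam10,ord04,3
sp041,fam10,ord04,3
sp042,fam10,ord04,3
sp043,fam11,ord05,3
sp044,fam12,ord05,1
sp045,fam12,ord05,1
sp046,fam12,ord05,3
sp047,fam12,ord05,3
sp048,fam12,ord05,3
sp049,fam13,ord06,3
sp050,fam13,ord06,3
sp051,fam13,ord06,3
sp052,fam14,ord06,1
sp053,fam14,ord06,3
sp054,fam14,ord06,2
sp055,fam14,ord06,3
sp056,fam15,ord07,3
sp057,fam15,ord07,3
sp058,fam15,ord07,3
sp059,fam16,ord07,1
sp060,fam16,ord07,3
sp061,fam16,ord07,2
sp062,fam16,ord07,3
sp063,fam17,ord08,3
sp064,fam17,ord08,3
sp065,fam17,ord08,3
sp066,fam17,ord08,1
sp067,fam17,ord08,3
sp068,fam18,ord08,3
sp069,fam18,ord08,3
sp070,fam18,ord08,1
sp071,fam18,ord08,3
sp072,fam18,ord08,3
sp073,fam18,ord08,3
sp074,fam19,ord09,3
sp075,fam20,ord09,3
sp076,fam20,ord09,3
sp077,fam20,ord09,2
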