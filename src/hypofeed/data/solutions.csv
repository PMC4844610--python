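AgRP.LepRB,AgRP.GHSR,AgRP.5HT1BR,POMC.LepRB,POMC.Y1R,POMC.GABAR,POMC.5HT2CR,NGABA.LepRB,OXT.MC3R,OXT.MC4R,OXT.GABAR,OXT.Y1R,OXT.MCHR,MCH.GLUR,OX.GLUR,OX.GHSR,OX.GalR,OX.AGRPR,OX.MCR,LHGal.LepRB,NT.LepRB,NTSCA.LepRB,NTSCA.GHSR,NTSCA.OXR,NTSCA.OXTR,NTSCA.CCKR,NTSGLP1.LepRB,NTSGLP1.AR,VTA.LepRB,VTA.GHSR,VTA.OXR,VTA.NTR,VTA.GLP1R,NAc.DR,NAc.Y1R,NAc.MCHR,NAc.GLP1R,FI.GABAR,AgRP.bias,POMC.bias,NGABA.bias,OXT.bias,MCH.bias,OX.bias,LHGal.bias,NT.bias,NTSCA.bias,NTSGLP1.bias,VTA.bias,NAc.bias,FI.bias,distance,source,member,error
0.12378177736834821,2.0853382525285107,0.14592250408758162,0.15890133002209156,0.42670816500497244,0.7486513603193703,3.1421959773167965,1.5344511367345208,1.749219048618392,1.7369917678385933,0.26569032623774824,0.30305254032009765,0.2866973107369692,0.21618366733193883,0.046278519309068886,0.3877467366340051,1.0898172757940696,0.8732878048629109,0.3709781863392066,0.8422425353573435,1.3422057307272626,0.7046997759907705,1.084412384460658,0.32253887412908777,1.0236258541414198,1.570953610904051,1.2303226829716305,0.031350668245576634,0.13096110989862433,0.07028331892254,1.276454217915143,0.19040499234861383,0.05800698120650151,0.221790904896485,0.5792153953775141,0.23124021615948284,0.8829355650136462,1.482439514376724,-1.5193728188844131,2.081397150357651,2.7929972146233726,-3.219749114483963,0.11670051534992472,2.3897099320643456,-0.17927918961569297,-0.3392267928558124,0.07940204337284999,-0.4281359005171175,1.7618678609651923,1.1423322832084573,2.826449144709522,9.147751796279017,analytic-seed+local-search,3,0
0.21310420374326272,2.0173055401120603,0.24860107278322924,0.1011539834200631,0.4782068281556942,0.5066694050923259,2.9100715913755235,1.6587343294925727,1.1888704456556773,1.172743527037484,0.10187526966989452,0.046292700441534745,0.0,0.364907539596255,0.0,0.3616389388524547,0.5575822652826468,0.9064043836788483,0.652190809277903,0.9222395700545237,1.2406439522730046,0.5836759558413513,0.3954097009341758,0.342336352974978,0.8332639164077164,1.7623233395164881,1.1785792492246179,0.20368352800809722,0.15215137558433037,0.20466930162604557,1.0385070483698713,0.15651443920828265,0.514550420059915,0.353099853970234,0.36278943496676125,0.07710073497503361,0.4780686671709595,0.8777441711172249,-0.89488990328459,2.066979955760446,3.561024778393148,-3.0890737446215057,0.47473875525266096,2.728879328846717,0.01762727488848044,-0.14686684237698364,-0.6254179841218147,-0.2564678137952321,1.43361041602671,2.390319614657485,3.1518878581675986,9.197535042436698,analytic-seed+local-search,5,0
0.24773827257371184,1.9711108198321807,0.2797469637445301,0.0781291075795377,0.3330336525572076,0.5833026977021746,2.8231231844017404,1.6432080777576719,1.2455474719078867,1.2841819888599884,0.023090074050224563,0.12581791610923607,0.0016604403707637166,0.5311685262976383,0.011001503984862611,0.3733305150286865,0.5058389117890068,0.9377629242839277,0.519133474519268,0.8969562648030853,1.3207489729812933,0.6376772526867697,0.49633216228634663,0.4661620937390372,0.8008629234037248,1.7461401976170263,1.2279920992148063,0.2597485015465951,0.11632834173338237,0.2572512967613293,0.9831163366963354,0.1008395803968994,0.38865265663908316,0.3628137100675063,0.45214766725731725,0.10661987289815117,0.5340900032571625,0.8539316100962575,-0.6665323973643089,2.560392937868361,3.6417688866663678,-3.150032201034734,0.5381854133994373,2.5713569103617724,0.060819973912766466,-0.28924787852554384,-0.5469101825458881,-0.42726351863702894,1.337517012826957,2.335143023322814,3.1527019014581246,9.289076780410621,analytic-seed+local-search,0,0
0.28250570620113274,1.9693690186999961,0.2828023728235501,0.0,0.2642523651711924,0.5955471495004229,2.913184175648608,1.7413957806760647,1.3423782458896125,1.1077930897005168,0.013155485589584633,0.12455928953149467,0.12150892019805362,0.6863831016189441,0.05809349979585173,0.705088464541009,0.7032595887134832,1.6948457207971348,0.523975450713557,0.6708917354026592,1.1250538833419954,0.5356736462165983,0.316798973541077,0.3658373797100499,0.8331995950040716,1.668187110372915,1.233400924814762,0.3421000454956464,0.1038588663415573,0.07770433169540121,0.7173892773941194,0.03883670808578647,0.217792426790821,0.29470344725149844,0.5000305804785086,0.2860499900862106,0.5395010008428334,0.9196822719745689,-0.560559608242349,2.685552006824121,3.6917935944427676,-3.243003814905213,0.5556279967970519,1.9900783237378066,-0.2727610887298764,-0.08569781202915198,-0.7689974066442241,-0.3273199619561698,1.3745293846287607,2.260095581381956,3.480920186209146,9.432892025986202,analytic-seed+local-search,2,0
0.22084634064542763,1.9631488246702318,0.26054691045539236,0.14803946226501175,0.25899032461462557,0.5874860832146106,2.826530239561901,1.7259147590408717,1.2194553780923714,0.998888754645171,0.03542694177545916,0.14031066629219935,0.03237528426524329,0.6744372504062035,0.0067548380882656335,0.3274707572284376,0.5325219768085623,0.9874263395094621,0.5873401215664633,0.9343640769310544,1.3177632030109112,0.44436581593382857,0.5299437136854779,0.42832731612633734,0.7806458702404733,1.6236540769013208,1.2830472005435853,0.2735348109739294,0.09505755944805082,0.22525446463114446,1.0608075247833284,0.14430401783597796,0.2706752818589756,0.33406933642086056,0.5283831938508405,0.2423060813466332,0.5122260408777423,0.8505489649014834,-0.7650474799767617,2.6498494578498106,3.7426406438922335,-2.9900737175940915,0.412937640014401,2.8271239237274335,0.08450486342833206,-0.24736531795067024,-0.47127479563966246,-0.5058376509438837,1.4462385491769985,2.7951354297414017,3.226047914360658,9.51703475370327,analytic-seed+local-search,1,0
0.22247146680223068,1.9326632019025094,0.2754836999046285,0.17949995188010381,0.392340722065809,0.6174408219037579,2.7967999055314197,1.6386514273179311,1.3796176328853176,1.4117964878399618,0.012816434708910956,0.3743192062405191,0.1857561807509284,0.5902675141233271,0.14403244089859946,0.22747694013890507,0.5635738009283467,0.9617395597832539,0.5011688654192521,0.9155522023738345,1.3551751066832158,0.8012803413034544,0.937504175133874,0.5252361667736359,0.8567855236909154,1.7516443450838923,1.3834600201987108,0.15607564141231112,0.8282215076271247,0.05417048741167201,0.9600582534397253,0.0681529185900736,0.3357038100284722,0.3655599007897046,0.41338085414567555,0.25475086542434533,0.5818453935241209,0.9254663282773348,-0.7295479234231748,2.7698561656168317,3.4942699125300223,-3.3022615870954497,0.6575399122638238,2.621517739587213,-0.7654612904049785,-0.5270803755439745,-0.4638823882936178,-1.1531310492932771,1.3748676230006494,2.5114982093830815,3.1031303869295677,9.65844890704862,analytic-seed+local-search,4,0
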