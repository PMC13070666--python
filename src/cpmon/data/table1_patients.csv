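patient_no,age,sex,location,bmi,frailty,pmh,pu_cat_pre,pu_location,mattress_pre,pu_cat_post,mattress_post,carer
1,74,F,Home,46.7,6,Osteo Arthritis,Cat 2,Buttock,Dynamic Air Overlay,Healed,Dynamic Air Overlay,1 time per day
2,92,F,Home,24.3,6,Dementia,Cat 2,Buttock,Dynamic Air Overlay,Healed,Static Air Overlay,Continuous
5,66,M,Home,32.9,7,MS,Cat 2,Buttock,Static Foam Mattress,Healed,Static Air Overlay,4 times per day
6,66,F,Home,32.0,6,SCI,Cat 2,Buttock,Own Mattress,Healed,Static Air Overlay,None
7,52,F,Home,25.5,6,MS,Unstageable,Hip,Static air Overlay,Healed,Air Floatation,Continuous
8,86,F,Home,15.1,8,CVE/Dementia,Unstageable,Sacrum,Dynamic Air Mattress,Unstageable,Dynamic Air Mattress,4 times per day
9,82,F,Home,37.5,6,CVE,Cat 2,Buttock,Dynamic Air Overlay,Healed,Air Floatation,4 times per day
10,30,M,Home,22.5,7,Spina Bifida,Cat 4,Spine,Dynamic Air Mattress,Healed,Dynamic Air Mattress + Turn Device,Continuous
11,65,F,Home,31.0,7,MS,Cat 2,Buttock,Static air Overlay,Healed,Own Mattress + Jay Hybrid,Continuous
12,71,F,Home,21.0,7,MS,Unstageable,IT,Powered Hybrid (Air and Foam),Healed,Dynamic Air Mattress + Turn Device,3 times per day
13,81,F,Home,24.0,8,Not recorded,Unstageable,Spine,Powered Hybrid (Air and Foam),Healing Cat 4,Dynamic Air Mattress + Turn Device,4 times per day
15,56,M,Home,37.9,5,SCI,Unstageable,Buttock,Static Foam Mattress,Healed,Air Floatation,2 times per day
16,82,F,Residential Home,17.3,7,Dementia,Healing Cat 4,Sacrum,Powered hybrid (Air and Foam),Healing Cat 4,Dynamic Air Mattress,Continuous
17,43,M,Home,19.6,7,Cerebral Palsy,Cat 3,Hip,Own Mattress,Healed,Air Floatation,Continuous
18,95,M,Home,23.1,7,SCI,Cat 2,Buttock,Static Foam Mattress,Cat 2,Air Floatation,2 times per day
19,68,F,Home,26.5,7,MS,Healed,N/A,Dynamic Air Mattress,Intact,Powered hybrid (Air and Foam),4 times per day
22,65,M,Home,23.1,7,SCI,Cat 2,IT,Powered hybrid (Air and Foam),Healed,Dynamic Air Overlay,3 times per day
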