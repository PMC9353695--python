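site,incident,detected_date,alert_datetime,published_improvement_days,date_resolution
A,1,11/9/2015,1/21/2015 8:19 pm,291,day
A,2,1/26/2015,1/1/2015 12:36 am,25,day
A,3,5/4/2016,3/9/2015 5:02 am,422,day
A,4,8/13/2015,1/9/2015 2:12 am,216,day
A,5,5/28/2017,2/14/2016 8:24 am,469,day
A,6,11/23/2016,10/25/2016 11:32 am,29,day
A,7,6/20/2016,1/17/2015 8:28 pm,519,day
A,8,5/28/2017,4/15/2017 9:27 am,43,day
A,9,12/13/2016,5/13/2015 11:19 pm,579,day
B,1,8/2/2018,"7/11/2018, 18:23",21,day
B,2,5/31/2018,"5/19/2018, 04:48",12,day
B,3,8/24/2018,"5/29/2018, 17:14",86,day
B,4,10/15/2018,"5/24/2018, 07:09",144,day
B,5,10/30/2018,"10/22/2018, 16:38",7,day
B,6,10/15/2018,"6/2/2018, 11:17",135,day
B,7,10/15/2018,"7/16/2018, 00:13",91,day
C,1,January 2018,November 2017,61,month
C,2,March 2017,January 2017,59,month
C,3,June 2017,January 2017,151,month
C,4,February 2017,January 2017,31,month
C,5,August 2017,June 2017,61,month
C,6,May 2017,March 2017,61,month
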